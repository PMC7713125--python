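"""Core-gene distance trees and the presence/absence pan-genome tree.

The core-gene tree follows the classic distance pipeline: concatenate
single-copy family alignments, compute Poisson-corrected distances
d = -ln(1 - p) from the proportion p of differing sites, build a
neighbor-joining starting tree, and refine it under the minimum-evolution
criterion with nearest-neighbor-interchange moves and OLS branch-length
re-estimation.  Column-resampling bootstrap attaches percent supports.

The pan-genome tree treats the 0/1 family presence matrix as unordered
discrete characters: with binary states, multistate parsimony reduces to
Fitch counting, searched here by random stepwise addition plus NNI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .msa import GAP, Alignment

__all__ = [
    "Alignment",
    "DistanceSaturationError",
    "concat_alignments",
    "distance_from_alignment",
    "concat_and_distance",
    "neighbor_joining",
    "ols_branch_lengths",
    "me_refine",
    "bootstrap_support",
    "fitch_counts",
    "fitch_score",
    "pan_parsimony_tree",
    "ParsimonyResult",
    "build_me_tree",
    "root_with_outgroup",
    "robinson_foulds",
    "write_tree",
    "read_tree",
]


class DistanceSaturationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


def concat_alignments(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate per-family alignments (cluster-id order) over shared taxa."""
    if not alignments:
        raise ValueError("no alignments to concatenate")

    def sort_key(aln: Alignment) -> str:
        if aln.column_sources:
            return aln.column_sources[0]
        return ""

    ordered = sorted(alignments, key=sort_key)
    taxa = sorted(ordered[0].ids)
    seqs = {t: [] for t in taxa}
    sources: list[str] = []
    for aln in ordered:
        if sorted(aln.ids) != taxa:
            raise ValueError("alignments must share the same taxon set")
        lookup = dict(zip(aln.ids, aln.seqs))
        for t in taxa:
            seqs[t].append(lookup[t])
        sources.extend(aln.column_sources or [""] * aln.n_columns)
    return Alignment(taxa, ["".join(seqs[t]) for t in taxa], sources)


def distance_from_alignment(
    alignment: Alignment, deletion: str = "complete"
) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) from an alignment.

    ``deletion='complete'`` compares only columns that are gap-free in all
    taxa; ``'pairwise'`` masks gaps per pair.  p >= 1 (fully saturated
    pair) is an error naming the offending pair.
    """
    taxa = alignment.ids
    arr = np.array([list(s) for s in alignment.seqs])
    nongap = arr != GAP
    n = len(taxa)
    d = np.zeros((n, n))
    if deletion == "complete":
        keep = nongap.all(axis=0)
        arr = arr[:, keep]
        nongap = nongap[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    for i in range(n):
        for j in range(i + 1, n):
            mask = nongap[i] & nongap[j]
            compared = int(mask.sum())
            if compared == 0:
                raise DistanceSaturationError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            p = float((arr[i, mask] != arr[j, mask]).sum()) / compared
            if p >= 1.0:
                raise DistanceSaturationError(
                    f"saturated distance (p={p:.3f}) between {taxa[i]} and {taxa[j]}"
                )
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(d, taxa)


def concat_and_distance(
    alignments: Sequence[Alignment], deletion: str = "complete"
) -> DistanceMatrix:
    return distance_from_alignment(concat_alignments(alignments), deletion)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break on the lexicographically smallest
    (representative-label) pair.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sister branch (the MEGA
    convention), preserving the joined pair's summed length.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False
    leaf_nodes = {}
    for name in ids:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(name)
        leaf_nodes[name] = node

    if n == 2:
        d = float(dm[ids[0], ids[1]])
        for name in ids:
            tree.seed_node.add_child(leaf_nodes[name])
            leaf_nodes[name].edge.length = d / 2.0
        return tree

    D = np.array(dm.data, dtype=float)
    nodes = [leaf_nodes[name] for name in ids]
    reps = list(ids)  # representative (smallest leaf label) per cluster

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - rowsum[i] - rowsum[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    a, b, c = range(3)
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, v in zip(nodes, (va, vb, vc)):
        tree.seed_node.add_child(node)
        node.edge.length = max(v, 0.0)
    return tree


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj = max(vj + vi, 0.0)
        vi = 0.0
    elif vj < 0:
        vi = max(vi + vj, 0.0)
        vj = 0.0
    return vi, vj


# ---------------------------------------------------------------------------
# minimum evolution by NNI with OLS branch lengths


def _edge_masks(tree: dendropy.Tree, taxa: Sequence[str]) -> tuple[list, np.ndarray]:
    """Per-edge boolean leaf masks (seed edge excluded)."""
    index = {t: i for i, t in enumerate(taxa)}
    edges = []
    masks = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        mask = np.zeros(len(taxa), dtype=bool)
        for leaf in edge.head_node.leaf_iter():
            mask[index[leaf.taxon.label]] = True
        edges.append(edge)
        masks.append(mask)
    return edges, np.array(masks)


def ols_branch_lengths(tree: dendropy.Tree, dm: DistanceMatrix) -> float:
    """OLS branch-length estimates written onto the tree; returns tree length.

    Tree length is the sum of branch lengths after clamping negative
    estimates to zero (the minimum-evolution objective used here).
    """
    taxa = list(dm.ids)
    edges, masks = _edge_masks(tree, taxa)
    n = len(taxa)
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        A[row] = masks[:, i] ^ masks[:, j]
        d[row] = dm.data[i, j]
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    lengths = np.maximum(b, 0.0)
    for edge, length in zip(edges, lengths):
        edge.length = float(length)
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None
    return float(lengths.sum())


def _nni_neighbors(tree: dendropy.Tree):
    """Yield trees one NNI move away (deterministic order).

    For each internal edge u-v (v an internal child of u), swapping a child
    of v with another child of u enumerates the alternative quartet
    arrangements around the edge.
    """
    base_edges = [
        i
        for i, edge in enumerate(tree.preorder_edge_iter())
        if edge.head_node is not tree.seed_node
        and not edge.head_node.is_leaf()
        and edge.tail_node is not None
    ]
    for edge_idx in base_edges:
        # count swap options on the original tree
        edge = list(tree.preorder_edge_iter())[edge_idx]
        v = edge.head_node
        u = edge.tail_node
        n_s = len(u.child_nodes()) - 1
        n_c = len(v.child_nodes())
        for si in range(n_s):
            for ci in range(n_c):
                clone = tree.clone(depth=1)
                cedge = list(clone.preorder_edge_iter())[edge_idx]
                cv = cedge.head_node
                cu = cedge.tail_node
                siblings = [ch for ch in cu.child_nodes() if ch is not cv]
                s = siblings[si]
                c = cv.child_nodes()[ci]
                cu.remove_child(s)
                cv.remove_child(c)
                cu.add_child(c)
                cv.add_child(s)
                yield clone


def me_refine(tree: dendropy.Tree, dm: DistanceMatrix) -> dendropy.Tree:
    """Hill-climb over NNI moves minimizing OLS tree length.

    Accepts only strictly improving moves, so the refined tree's length
    never exceeds the input's; stops at a local optimum.
    """
    current = tree.clone(depth=1)
    current_len = ols_branch_lengths(current, dm)
    improved = True
    while improved:
        improved = False
        best_tree, best_len = None, current_len
        for candidate in _nni_neighbors(current):
            length = ols_branch_lengths(candidate, dm)
            if length < best_len - 1e-10:
                best_tree, best_len = candidate, length
        if best_tree is not None:
            current, current_len = best_tree, best_len
            improved = True
    return current


def build_me_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """NJ starting tree refined under minimum evolution."""
    return me_refine(neighbor_joining(dm), dm)


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Edge]:
    """Canonical leaf-set keys for internal edges of an unrooted tree."""
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(all_leaves)
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            continue
        key = side if anchor not in side else frozenset(all_leaves - side)
        out[key] = edge
    return out


def bootstrap_support(
    alignments: Sequence[Alignment],
    tree_builder: Callable[[DistanceMatrix], dendropy.Tree] | None = None,
    replicates: int = 500,
    seed: int = 0,
    deletion: str = "complete",
) -> dendropy.Tree:
    """Column-resampling bootstrap supports on the distance tree.

    Rebuilds the tree on each resampled concatenated alignment and labels
    each internal edge of the full-data tree with the percentage of
    replicates containing its bipartition.  Replicates whose resampled
    distances saturate are skipped (and excluded from the denominator).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    builder = tree_builder or build_me_tree
    concat = concat_alignments(alignments)
    reference = builder(distance_from_alignment(concat, deletion))
    ref_biparts = _bipartitions(reference)
    counts = {key: 0 for key in ref_biparts}
    rng = np.random.default_rng(seed)
    arr = np.array([list(s) for s in concat.seqs])
    succeeded = 0
    for _ in range(replicates):
        cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
        resampled = Alignment(concat.ids, ["".join(row) for row in arr[:, cols]])
        try:
            rep_tree = builder(distance_from_alignment(resampled, deletion))
        except DistanceSaturationError:
            continue
        succeeded += 1
        rep_biparts = _bipartitions(rep_tree)
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    for key, edge in ref_biparts.items():
        pct = 100.0 * counts[key] / succeeded if succeeded else 0.0
        edge.head_node.label = str(int(round(pct)))
    return reference


# ---------------------------------------------------------------------------
# pan-genome parsimony tree (binary Fitch)


ABSENT, PRESENT = 1, 2  # Fitch state-set bit encoding


def fitch_counts(tree: dendropy.Tree, presence: pd.DataFrame) -> np.ndarray:
    """Per-family Fitch parsimony change counts of 0/1 characters on a tree.

    ``presence`` is families x genomes.  Characters are scored jointly as
    bitmask arrays; constant families contribute zero by construction.
    """
    leaf_states = {
        g: np.where(presence[g].values > 0, PRESENT, ABSENT).astype(np.uint8)
        for g in presence.columns
    }
    changes = np.zeros(presence.shape[0], dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = leaf_states[node.taxon.label]
            continue
        children = node.child_nodes()
        acc = state.pop(id(children[0]))
        for child in children[1:]:
            nxt = state.pop(id(child))
            inter = acc & nxt
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | nxt, inter).astype(np.uint8)
        state[id(node)] = acc
    return changes


def fitch_score(tree: dendropy.Tree, presence: pd.DataFrame) -> int:
    """Total Fitch parsimony score (sum of per-family change counts)."""
    return int(fitch_counts(tree, presence).sum())


@dataclass(frozen=True)
class ParsimonyResult:
    tree: dendropy.Tree
    score: int


def _attach_leaf_candidates(tree: dendropy.Tree, label: str):
    """Yield copies of the tree with ``label`` attached on each edge."""
    n_edges = sum(
        1 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )
    for edge_idx in range(n_edges):
        clone = tree.clone(depth=1)
        edges = [
            e for e in clone.preorder_edge_iter() if e.head_node is not clone.seed_node
        ]
        edge = edges[edge_idx]
        child = edge.head_node
        parent = edge.tail_node
        parent.remove_child(child)
        middle = parent.new_child()
        middle.add_child(child)
        leaf = middle.new_child()
        leaf.taxon = clone.taxon_namespace.require_taxon(label)
        yield clone


def pan_parsimony_tree(
    presence: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    nni: bool = True,
) -> ParsimonyResult:
    """Heuristic parsimony search on the binary presence matrix.

    Random-order stepwise addition followed by NNI hill-climbing, repeated
    over restarts; the best-scoring unrooted tree is returned with its
    score.  An all-constant matrix yields a star tree (score 0) with a
    warning.
    """
    genomes = sorted(presence.columns)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    presence = presence[genomes]
    variable = presence.loc[presence.nunique(axis=1) > 1]
    if variable.empty:
        warnings.warn("no variable families: returning a star tree", RuntimeWarning)
        taxa = dendropy.TaxonNamespace()
        star = dendropy.Tree(taxon_namespace=taxa)
        star.is_rooted = False
        for g in genomes:
            child = star.seed_node.new_child()
            child.taxon = taxa.new_taxon(g)
        return ParsimonyResult(star, 0)

    rng = np.random.default_rng(seed)
    best: ParsimonyResult | None = None
    for _ in range(max(1, n_restarts)):
        order = [genomes[i] for i in rng.permutation(len(genomes))]
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.is_rooted = False
        for g in order[:3]:
            child = tree.seed_node.new_child()
            child.taxon = taxa.new_taxon(g)
        for label in order[3:]:
            best_cand, best_sc = None, None
            for cand in _attach_leaf_candidates(tree, label):
                sc = fitch_score(cand, variable)
                if best_sc is None or sc < best_sc:
                    best_cand, best_sc = cand, sc
            tree = best_cand
        score = fitch_score(tree, variable)
        if nni:
            improved = True
            while improved:
                improved = False
                for cand in _nni_neighbors(tree):
                    sc = fitch_score(cand, variable)
                    if sc < score:
                        tree, score = cand, sc
                        improved = True
                        break
        if best is None or score < best.score:
            best = ParsimonyResult(tree, score)
    return best


# ---------------------------------------------------------------------------
# helpers


def root_with_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root an unrooted tree on the edge above the outgroup's MRCA."""
    rooted = tree.clone(depth=1)
    labels = list(outgroup)
    if len(labels) == 1:
        node = next(
            l for l in rooted.leaf_node_iter() if l.taxon.label == labels[0]
        )
    else:
        node = rooted.mrca(taxon_labels=labels)
        if node is rooted.seed_node:
            # outgroup spans the seed; root on the complement's MRCA instead
            others = [
                l.taxon.label
                for l in rooted.leaf_node_iter()
                if l.taxon.label not in set(labels)
            ]
            node = rooted.mrca(taxon_labels=others)
    length = node.edge.length or 0.0
    rooted.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    rooted.is_rooted = True
    return rooted


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unrooted symmetric-difference (RF) distance via shared bipartitions."""
    ba, bb = set(_bipartitions(a)), set(_bipartitions(b))
    return len(ba ^ bb)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path: str | Path, rooted: bool = False) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = rooted
    return tree
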
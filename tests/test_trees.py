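"""Distance computation, NJ, minimum-evolution refinement, bootstrap, and
the presence/absence parsimony tree."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from scipy.cluster.hierarchy import linkage, to_tree

from pancestry.msa import Alignment
from pancestry.trees import (
    DistanceSaturationError,
    ParsimonyResult,
    bootstrap_support,
    build_me_tree,
    concat_alignments,
    concat_and_distance,
    distance_from_alignment,
    fitch_counts,
    fitch_score,
    me_refine,
    neighbor_joining,
    ols_branch_lengths,
    pan_parsimony_tree,
    robinson_foulds,
    root_with_outgroup,
)


def splits(tree: dendropy.Tree) -> set[frozenset]:
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, frozenset(leaves - side), key=sorted))
    return out


def leaf_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for t1, t2 in itertools.combinations(taxa, 2):
        out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


class TestPoissonDistance:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b"], ["MKVL", "MKVL"])
        dm = distance_from_alignment(aln)
        assert dm["a", "b"] == 0.0

    def test_closed_form_for_ten_percent_difference(self):
        aln = Alignment(["a", "b"], ["A" * 9 + "C", "A" * 10])
        dm = distance_from_alignment(aln)
        assert dm["a", "b"] == pytest.approx(0.105360516, abs=1e-9)

    def test_matches_independent_site_count_oracle(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACDE-"), 40)) for _ in range(4)]
        ids = list("wxyz")
        aln = Alignment(ids, seqs)
        dm = distance_from_alignment(aln, deletion="pairwise")
        for i, j in itertools.combinations(range(4), 2):
            diffs = comp = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a != "-" and b != "-":
                    comp += 1
                    diffs += a != b
            assert dm[ids[i], ids[j]] == pytest.approx(-np.log(1 - diffs / comp))

    def test_complete_deletion_drops_gapped_columns(self):
        aln = Alignment(["a", "b"], ["MK-L", "MKVL"])
        # column 3 is dropped, remaining 3 columns identical
        assert distance_from_alignment(aln, "complete")["a", "b"] == 0.0

    def test_saturation_error_names_pair(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(DistanceSaturationError, match="a and b"):
            distance_from_alignment(aln)

    def test_concat_requires_shared_taxa(self):
        a = Alignment(["x", "y"], ["MK", "MK"], ["C1", "C1"])
        b = Alignment(["x", "z"], ["MK", "MK"], ["C2", "C2"])
        with pytest.raises(ValueError):
            concat_alignments([a, b])

    def test_concat_orders_by_cluster_id(self):
        a = Alignment(["x", "y"], ["MK", "MK"], ["C2", "C2"])
        b = Alignment(["x", "y"], ["VL", "VL"], ["C1", "C1"])
        cat = concat_alignments([a, b])
        assert cat.column_sources == ["C1", "C1", "C2", "C2"]
        assert cat.seqs[cat.ids.index("x")] == "VLMK"


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # ((a:2,b:3):1,(c:4,d:5)) with internal edge 1
        d = {
            ("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
            ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9,
        }
        ids = list("abcd")
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(mat, ids))
        assert splits(tree) == {frozenset({"a", "b"})}
        got = leaf_distances(tree)
        for (x, y), v in d.items():
            assert got[(x, y)] == pytest.approx(v)

    def test_three_taxa_closed_form(self):
        mat = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(mat, list("abc")))
        lengths = {
            n.taxon.label: n.edge.length for n in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"]))
        assert leaf_distances(tree)[("a", "b")] == pytest.approx(3.0)

    def test_ultrametric_matches_upgma_topology(self):
        rng = np.random.default_rng(6)
        # random ultrametric distances via a random UPGMA-like hierarchy
        n = 7
        ids = [f"t{i}" for i in range(n)]
        points = rng.normal(size=(n, 1))
        raw = np.abs(points - points.T)
        Z = linkage(raw[np.triu_indices(n, 1)], method="average")
        # cophenetic distances are exactly ultrametric
        from scipy.cluster.hierarchy import cophenet

        coph = cophenet(Z)
        mat = np.zeros((n, n))
        mat[np.triu_indices(n, 1)] = coph
        mat += mat.T
        nj_tree = neighbor_joining(DistanceMatrix(mat, ids))

        def upgma_splits(node, acc):
            if node.is_leaf():
                return {ids[node.id]}
            left = upgma_splits(node.left, acc)
            right = upgma_splits(node.right, acc)
            clade = left | right
            if 1 < len(clade) < n - 1:
                acc.add(min(frozenset(clade), frozenset(set(ids) - clade), key=sorted))
            return clade

        acc: set[frozenset] = set()
        upgma_splits(to_tree(Z), acc)
        assert splits(nj_tree) == acc

    def test_agrees_with_skbio_on_random_matrices(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 6
            points = rng.normal(size=(n, 4))
            mat = np.linalg.norm(points[:, None] - points[None, :], axis=2)
            ids = [f"t{i}" for i in range(n)]
            dm = DistanceMatrix(mat, ids)
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm)
            theirs_dp = dendropy.Tree.get(data=str(theirs), schema="newick")
            assert robinson_foulds(ours, theirs_dp) == 0


class TestMinimumEvolution:
    @staticmethod
    def random_additive(rng, n=5):
        """A random binary tree's additive distance matrix plus the tree splits."""
        ids = [f"t{i}" for i in range(n)]
        tree = dendropy.Tree.get(
            data="(((t0,t1),t2),(t3,t4));", schema="newick"
        )
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length = float(rng.uniform(0.5, 2.0))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            mat[i, j] = mat[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
        return DistanceMatrix(mat, ids), tree

    def test_additive_input_is_fixed_point(self):
        rng = np.random.default_rng(3)
        dm, true_tree = self.random_additive(rng)
        nj = neighbor_joining(dm)
        refined = me_refine(nj, dm)
        assert robinson_foulds(refined, nj) == 0
        assert robinson_foulds(refined, true_tree) == 0

    def test_refinement_never_increases_length(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = 6
            points = rng.normal(size=(n, 3))
            mat = np.linalg.norm(points[:, None] - points[None, :], axis=2)
            dm = DistanceMatrix(mat, [f"t{i}" for i in range(n)])
            start = neighbor_joining(dm)
            before = ols_branch_lengths(start, dm)
            after = ols_branch_lengths(me_refine(start, dm), dm)
            assert after <= before + 1e-9

    def test_reaches_exhaustive_minimum_on_most_five_taxon_instances(self):
        rng = np.random.default_rng(21)
        wins = 0
        trials = 100
        for _ in range(trials):
            points = rng.normal(size=(5, 3))
            mat = np.linalg.norm(points[:, None] - points[None, :], axis=2)
            dm = DistanceMatrix(mat, list("abcde"))
            refined_len = ols_branch_lengths(build_me_tree(dm), dm)
            best = min(
                _independent_ols_length(top, dm) for top in five_taxon_topologies()
            )
            if refined_len <= best + 1e-9:
                wins += 1
        assert wins >= 90

    def test_three_clean_clades_bootstrap(self):
        # two divergent clades, many sites: all supports saturate at 100
        block = 60
        seqs = {
            "a1": "A" * block + "C" * block,
            "a2": "A" * block + "C" * block,
            "b1": "A" * block + "Y" * block,
            "b2": "A" * block + "Y" * block,
        }
        # slight within-clade variation keeps distances finite and unequal
        seqs["a2"] = "G" + seqs["a2"][1:]
        seqs["b2"] = "G" + seqs["b2"][1:]
        aln = Alignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
        tree = bootstrap_support([aln], replicates=50, seed=4)
        labels = [
            int(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert labels and all(v == 100 for v in labels)

    def test_bootstrap_invariant_to_leaf_order(self):
        rng = np.random.default_rng(17)
        cols = rng.choice(list("ACDEFG"), size=(5, 80))
        ids = [f"t{i}" for i in range(5)]
        fwd = Alignment(ids, ["".join(r) for r in cols])
        perm = [3, 1, 4, 0, 2]
        rev = Alignment([ids[i] for i in perm], ["".join(cols[i]) for i in perm])
        t1 = bootstrap_support([fwd], replicates=30, seed=9)
        t2 = bootstrap_support([rev], replicates=30, seed=9)

        def support_map(tree):
            return {
                frozenset(l.taxon.label for l in n.leaf_iter()): n.label
                for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.label is not None
            }

        assert support_map(t1) == support_map(t2)


def five_taxon_topologies():
    """All 15 unrooted 5-taxon topologies as Newick strings."""
    out = []
    seen_splits = set()
    quartets = ["((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));"]
    for q in quartets:
        tree = dendropy.Tree.get(data=q, schema="newick")
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        ]
        for idx in range(len(edges)):
            t2 = tree.clone(depth=1)
            e2 = [
                e for e in t2.preorder_edge_iter() if e.head_node is not t2.seed_node
            ][idx]
            child = e2.head_node
            parent = e2.tail_node
            parent.remove_child(child)
            mid = parent.new_child()
            mid.add_child(child)
            leaf = mid.new_child()
            leaf.taxon = t2.taxon_namespace.require_taxon("e")
            t2.is_rooted = False
            key = frozenset(splits(t2))
            if key not in seen_splits:
                seen_splits.add(key)
                out.append(t2)
    assert len(out) == 15
    return out


def _independent_ols_length(tree: dendropy.Tree, dm: DistanceMatrix) -> float:
    """OLS tree length computed from scratch (path-incidence least squares)."""
    ids = list(dm.ids)
    index = {t: i for i, t in enumerate(ids)}
    edges = [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    ]
    masks = []
    for e in edges:
        m = np.zeros(len(ids), dtype=bool)
        for l in e.head_node.leaf_iter():
            m[index[l.taxon.label]] = True
        masks.append(m)
    pairs = list(itertools.combinations(range(len(ids)), 2))
    A = np.array([[mk[i] ^ mk[j] for mk in masks] for i, j in pairs], dtype=float)
    d = np.array([dm.data[i, j] for i, j in pairs])
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    return float(np.maximum(b, 0).sum())


class TestPanParsimony:
    def test_autapomorphy_contributes_one(self):
        df = pd.DataFrame({"g1": [1], "g2": [0], "g3": [0], "g4": [0]}, index=["F1"])
        tree = dendropy.Tree.get(data="((g1,g2),(g3,g4));", schema="newick")
        assert fitch_score(tree, df) == 1

    def test_constant_families_contribute_zero(self):
        df = pd.DataFrame(
            {"g1": [1, 0], "g2": [1, 0], "g3": [1, 0]}, index=["F1", "F2"]
        )
        tree = dendropy.Tree.get(data="(g1,(g2,g3));", schema="newick")
        assert fitch_score(tree, df) == 0

    def test_per_family_counts_sum_to_score(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.integers(0, 2, size=(30, 5)),
            index=[f"F{i}" for i in range(30)],
            columns=[f"g{i}" for i in range(5)],
        )
        tree = dendropy.Tree.get(data="((g0,g1),(g2,g3),g4);", schema="newick")
        counts = fitch_counts(tree, df)
        assert counts.sum() == fitch_score(tree, df)

    def test_all_constant_matrix_gives_star_tree(self):
        df = pd.DataFrame(
            {"g1": [1, 1], "g2": [1, 1], "g3": [1, 1], "g4": [1, 1]},
            index=["F1", "F2"],
        )
        with pytest.warns(RuntimeWarning):
            result = pan_parsimony_tree(df, n_restarts=2, seed=0)
        assert result.score == 0
        assert len(result.tree.seed_node.child_nodes()) == 4

    def test_true_tree_scores_better_than_most_random_topologies(self, sim12):
        from pancestry.panmatrix import pan_matrix_from_presence

        hist = sim12.history
        m = pan_matrix_from_presence(hist.node_families, hist.leaf_labels())
        presence = m.presence()
        true_score = fitch_score(hist.tree, presence)
        rng = np.random.default_rng(0)
        labels = hist.leaf_labels()
        worse = 0
        trials = 40
        for _ in range(trials):
            shuffled = [labels[i] for i in rng.permutation(len(labels))]
            relabeled = hist.tree.clone(depth=1)
            for leaf, new in zip(relabeled.leaf_node_iter(), shuffled):
                leaf.taxon = relabeled.taxon_namespace.require_taxon(new)
            # random relabelling destroys the match between tree and data
            score = fitch_score(relabeled, presence)
            worse += score >= true_score
        assert worse >= 0.95 * trials


class TestRooting:
    def test_outgroup_rooting_splits_at_outgroup(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1,e:3);", schema="newick")
        tree.is_rooted = False
        rooted = root_with_outgroup(tree, ["e"])
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
        assert {"e"} in sides
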
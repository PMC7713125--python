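"""Synthetic pangenomes with known gene-content histories.

A pangenome is simulated in three steps: a Yule (pure-birth) genome tree,
a gain/loss process for gene-family content along its branches, and protein
sequences for every family member.  Because the full history is retained,
every downstream stage (clustering, partitioning, tree building, ancestral
reconstruction) can be scored against exact ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ROOT_BRANCH = "root"


class InvalidConfigError(ValueError):
    pass


class InvalidTreeError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated pangenome.

    Defaults describe a desk-scale open pangenome: a dozen genomes, a few
    hundred gene families at steady state (gain/loss balanced so leaves stay
    near the root size), and within-family divergence low enough that family
    members remain clearly more similar to each other (~85-90 % identity)
    than to background (~5-10 %).

    Rates are per unit branch length on a tree rescaled to height
    ``tree_height`` (set ``tree_height=None`` to keep raw Yule heights).
    """

    n_genomes: int = 12
    birth_rate: float = 1.0
    root_families: int = 300
    gain_rate: float = 30.0
    loss_rate: float = 0.1
    mean_protein_len: int = 150
    substitution_rate: float = 0.075
    target_genes_per_genome_range: tuple[int, int] = (200, 450)
    duplication_prob: float = 0.0
    tree_height: float | None = 1.0
    min_protein_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise InvalidConfigError("n_genomes must be >= 2")
        for name in ("birth_rate", "root_families", "mean_protein_len"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("gain_rate", "loss_rate", "substitution_rate", "duplication_prob"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        lo, hi = self.target_genes_per_genome_range
        if lo > hi:
            raise InvalidConfigError("target_genes_per_genome_range low > high")
        if self.tree_height is not None and self.tree_height <= 0:
            raise InvalidConfigError("tree_height must be > 0 or None")


@dataclass
class TrueHistory:
    """Ground-truth gene-content history on a rooted genome tree.

    ``node_families`` maps every node label to the family-id set present
    there; ``branch_events`` maps a child node label to the (gains, losses)
    that occurred on the branch leading into it; ``family_birth_branch``
    records on which branch each family arose ("root" for root families).
    """

    tree: dendropy.Tree
    node_families: dict[str, frozenset[str]]
    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]]
    family_birth_branch: dict[str, str]

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.family_birth_branch)

    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())


@dataclass
class SimulatedPangenome:
    """Proteomes plus the history that produced them."""

    proteomes: dict[str, list[tuple[str, str, str]]]  # genome -> (pid, fam, seq)
    history: TrueHistory


def _label_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        else:
            i += 1
            node.label = f"n{i}"


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Simulate a rooted binary Yule tree with ``n_genomes`` leaves.

    Lineages split at rate ``birth_rate`` each; with k extant lineages the
    next split arrives after Exp(k*birth_rate).  Simulation stops at the
    (n+1)-th split epoch, so the expected root-to-tip height is
    sum_{k=2..n} 1/(k*birth_rate).  If ``config.tree_height`` is set the
    tree is rescaled to exactly that height.
    """
    if config.n_genomes < 2:
        raise InvalidConfigError("n_genomes must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, lam = config.n_genomes, config.birth_rate

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    k = 2
    while True:
        t = rng.exponential(1.0 / (k * lam))
        for node in active:
            node.edge.length += t
        if k == n:
            break
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            active.append(child)
        k += 1
    for i, node in enumerate(sorted(active, key=lambda nd: _node_sort_key(nd)), start=1):
        taxon = taxa.new_taxon(f"g{i:03d}")
        node.taxon = taxon
    if config.tree_height is not None:
        height = max(l.distance_from_root() for l in tree.leaf_node_iter())
        scale = config.tree_height / height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    _label_nodes(tree)
    return tree


def _node_sort_key(node: dendropy.Node) -> tuple:
    # Stable left-to-right order of leaves for deterministic labelling.
    path = []
    while node.parent_node is not None:
        path.append(node.parent_node.child_nodes().index(node))
        node = node.parent_node
    return tuple(reversed(path))


def evolve_gene_content(
    tree: dendropy.Tree, config: SimConfig, rng: np.random.Generator | None = None
) -> TrueHistory:
    """Evolve gene-family presence along the tree.

    The root carries ``root_families`` families.  On a branch of length t,
    Poisson(gain_rate*t) new families arise (uniformly along the branch,
    each surviving its remainder under the loss rate) and each inherited
    family is lost independently with probability 1 - exp(-loss_rate*t).
    The recorded gains are the families actually present at the child, so
    mean leaf content follows the continuous birth-death expectation
    R*exp(-l*T) + (g/l)*(1 - exp(-l*T)) on an ultrametric tree of height T.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InvalidTreeError("negative branch length")

    counter = [0]

    def new_family() -> str:
        counter[0] += 1
        return f"F{counter[0]:06d}"

    root = tree.seed_node
    node_families: dict[str, frozenset[str]] = {}
    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    family_birth_branch: dict[str, str] = {}

    root_set = frozenset(new_family() for _ in range(config.root_families))
    for fid in root_set:
        family_birth_branch[fid] = ROOT_BRANCH
    node_families[root.label] = root_set

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        inherited = sorted(node_families[node.parent_node.label])
        p_loss = 1.0 - math.exp(-config.loss_rate * t)
        lost = frozenset(
            fid for fid in inherited if rng.random() < p_loss
        )
        # gains arrive uniformly along the branch and must survive its
        # remainder, matching the continuous gain/loss process exactly
        n_events = int(rng.poisson(config.gain_rate * t))
        gained_list = []
        for _ in range(n_events):
            u = rng.uniform(0.0, t)
            if rng.random() < math.exp(-config.loss_rate * (t - u)):
                gained_list.append(new_family())
        gained = frozenset(gained_list)
        for fid in sorted(gained):
            family_birth_branch[fid] = node.label
        node_families[node.label] = (frozenset(inherited) - lost) | gained
        branch_events[node.label] = (gained, lost)

    return TrueHistory(tree, node_families, branch_events, family_birth_branch)


def _sample_length(config: SimConfig, rng: np.random.Generator) -> int:
    spread = config.mean_protein_len - config.min_protein_len
    if spread <= 0:
        return config.min_protein_len
    return config.min_protein_len + int(rng.geometric(1.0 / spread)) - 1


def _mutate(seq: str, t: float, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or t <= 0:
        return seq
    n_events = int(rng.poisson(rate * t * len(seq)))
    if n_events == 0:
        return seq
    chars = list(seq)
    sites = rng.integers(0, len(chars), size=n_events)
    draws = rng.integers(0, 19, size=n_events)
    for site, draw in zip(sites, draws):
        old_idx = AMINO_ACIDS.index(chars[site])
        repl_idx = int(draw) + (1 if draw >= old_idx else 0)  # uniform over the 19 others
        chars[site] = AMINO_ACIDS[repl_idx]
    return "".join(chars)


def emit_proteomes(
    history: TrueHistory, config: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedPangenome:
    """Sample protein sequences for every family member.

    Each family gets one ancestral sequence at its branch of origin
    (uniform residue composition, geometric length, minimum
    ``min_protein_len``); copies then accumulate Poisson substitutions
    proportional to the path length down to each leaf.  Distinct families
    are sampled independently, so inter-family identity stays near the
    1/20 background.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    tree = history.tree
    nodes = {n.label: n for n in tree.preorder_node_iter()}

    proteomes: dict[str, list[tuple[str, str, str]]] = {
        leaf: [] for leaf in history.leaf_labels()
    }

    for fid in history.family_ids:
        birth = history.family_birth_branch[fid]
        birth_node = tree.seed_node if birth == ROOT_BRANCH else nodes[birth]
        ancestral = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=_sample_length(config, rng))
        )
        # depth-first descent restricted to nodes where the family survives
        stack = [(birth_node, ancestral)]
        while stack:
            node, seq = stack.pop()
            if fid not in history.node_families[node.label]:
                continue
            if node.is_leaf():
                genome = node.taxon.label
                pid = f"{genome}|{fid}"
                proteomes[genome].append((pid, fid, seq))
                if config.duplication_prob > 0 and rng.random() < config.duplication_prob:
                    proteomes[genome].append((f"{pid}.2", fid, seq))
                continue
            for child in reversed(node.child_nodes()):
                child_seq = _mutate(seq, child.edge.length or 0.0, config.substitution_rate, rng)
                stack.append((child, child_seq))

    for genome in proteomes:
        proteomes[genome].sort()
    return SimulatedPangenome(proteomes, history)


def simulate_pangenome(config: SimConfig) -> SimulatedPangenome:
    """Run all three simulation stages with seeds derived from the config."""
    tree = simulate_tree(config)
    history = evolve_gene_content(tree, config)
    return emit_proteomes(history, config)


# ---------------------------------------------------------------------------
# on-disk formats


def write_proteomes(pangenome: SimulatedPangenome, outdir: str | Path) -> list[Path]:
    """One FASTA per genome; headers carry the true family id for evaluation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome in sorted(pangenome.proteomes):
        path = outdir / f"{genome}.faa"
        with open(path, "w") as fh:
            for pid, fid, seq in pangenome.proteomes[genome]:
                fh.write(f">{pid} family={fid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths.append(path)
    return paths


def read_proteomes(indir: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read per-genome FASTA files; returns genome -> [(protein id, seq)]."""
    from Bio import SeqIO

    indir = Path(indir)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for path in sorted(indir.glob("*.faa")):
        genome = path.stem
        proteomes[genome] = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        ]
    return proteomes


def true_family_labels(indir: str | Path) -> dict[str, str]:
    """Extract protein-id -> true-family-id from simulation FASTA headers."""
    from Bio import SeqIO

    labels = {}
    for path in sorted(Path(indir).glob("*.faa")):
        for rec in SeqIO.parse(str(path), "fasta"):
            for token in rec.description.split():
                if token.startswith("family="):
                    labels[rec.id] = token.split("=", 1)[1]
    return labels


def write_truth(history: TrueHistory, path: str | Path) -> None:
    payload = {
        "tree": history.tree.as_string(schema="newick").strip(),
        "node_families": {k: sorted(v) for k, v in sorted(history.node_families.items())},
        "branch_events": {
            k: {"gained": sorted(g), "lost": sorted(l)}
            for k, (g, l) in sorted(history.branch_events.items())
        },
        "family_birth_branch": dict(sorted(history.family_birth_branch.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> TrueHistory:
    payload = json.loads(Path(path).read_text())
    tree = dendropy.Tree.get(data=payload["tree"], schema="newick")
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
    return TrueHistory(
        tree,
        {k: frozenset(v) for k, v in payload["node_families"].items()},
        {
            k: (frozenset(v["gained"]), frozenset(v["lost"]))
            for k, v in payload["branch_events"].items()
        },
        payload["family_birth_branch"],
    )


def write_qc_table(
    genome_ids: Iterable[str],
    path: str | Path,
    fail_ids: Iterable[str] = (),
    seed: int = 0,
) -> None:
    """QC table (genome_id, completeness, contamination) with planted failures.

    Passing genomes draw completeness in (99, 100] and contamination in
    [0, 3); planted failures draw completeness in [60, 95) and contamination
    in [6, 15), so they fail both the >99 and <5 criteria.
    """
    rng = np.random.default_rng(seed)
    fail = set(fail_ids)
    with open(path, "w") as fh:
        fh.write("genome_id\tcompleteness\tcontamination\n")
        for gid in sorted(set(genome_ids)):
            if gid in fail:
                comp = 60 + 35 * rng.random()
                cont = 6 + 9 * rng.random()
            else:
                comp = 99.01 + 0.99 * rng.random()
                cont = 3 * rng.random()
            fh.write(f"{gid}\t{comp:.2f}\t{cont:.2f}\n")
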
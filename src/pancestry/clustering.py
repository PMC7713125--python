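"""OMCL-style orthology: all-vs-all similarity, bidirectional best hits,
and Markov clustering of the resulting protein graph into gene families.

The decision contract follows the classic GET_HOMOLOGUES/OrthoMCL recipe:
hits are kept when they pass coverage (default 75 % on both query and
subject), E-value (default 1e-10) and optional identity thresholds;
reciprocal best hits between genomes define an undirected graph weighted by
-log10(E); Markov clustering (expansion/inflation iteration) partitions the
graph into ortholog/paralog clusters.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .alignment import (
    EValueCalibration,
    calibrate_evalue,
    estimate_evalue,
    local_align_score,
    make_aligner,
)

EVALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: float
    evalue: float
    query_coverage: float  # fraction of the query inside the aligned span
    percent_identity: float
    subject_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError("query_coverage must be in [0, 1]")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")


@dataclass(frozen=True)
class HitFilterConfig:
    min_coverage: float = 0.75
    max_evalue: float = 1e-10
    min_identity: float = 0.0  # set to 30 for the HGT-screen mode
    require_both_coverage: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.max_evalue < 0 or not 0 <= self.min_identity <= 100:
            raise ValueError("invalid filter thresholds")


#: Hit filter used for the reverse-search screen for candidate horizontal
#: transfers: minimum 30 % identity on top of the E-value cutoff.
HGT_SCREEN_FILTER = HitFilterConfig(min_coverage=0.0, max_evalue=1e-10, min_identity=30.0)


@dataclass(frozen=True)
class MclConfig:
    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    self_loops: bool = True

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2 or self.max_iterations < 1 or self.convergence_tol < 0:
            raise ValueError("invalid MCL configuration")


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: tuple[tuple[str, str], ...]  # (genome id, protein id)
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be nonempty")
        pids = [pid for _, pid in self.members]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate members")
        if self.representative not in pids:
            raise ValueError("representative must be a member")

    @property
    def protein_ids(self) -> list[str]:
        return [pid for _, pid in self.members]


# ---------------------------------------------------------------------------
# all-vs-all similarity search


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    calibration: EValueCalibration | None = None,
    aligner=None,
    k: int = 4,
    min_shared_kmers: int = 4,
) -> list[SimilarityHit]:
    """Score candidate protein pairs across (and within) all proteomes.

    A cheap shared k-mer prefilter selects candidate pairs; survivors are
    aligned with Smith-Waterman and assigned Karlin-Altschul E-values with
    the total residue count of all proteomes as the search space.  Both
    orientations of each scored pair are emitted so per-query best hits can
    be read off directly.
    """
    aligner = aligner or make_aligner()
    if calibration is None:
        calibration = calibrate_evalue(aligner)
    seqs: dict[str, str] = {}
    for genome in sorted(proteomes):
        for pid, seq in proteomes[genome]:
            if pid in seqs:
                raise ValueError(f"duplicate protein id {pid}")
            seqs[pid] = seq
    database_size = sum(len(s) for s in seqs.values())

    index: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(seqs):
        for kmer in _kmer_set(seqs[pid], k):
            index[kmer].append(pid)

    pairs: set[tuple[str, str]] = set()
    for pid in sorted(seqs):
        shared: dict[str, int] = defaultdict(int)
        for kmer in _kmer_set(seqs[pid], k):
            for other in index[kmer]:
                if other > pid:
                    shared[other] += 1
        for other, count in shared.items():
            if count >= min_shared_kmers:
                pairs.add((pid, other))

    hits: list[SimilarityHit] = []
    for a, b in sorted(pairs):
        aln = local_align_score(seqs[a], seqs[b], aligner)
        if aln.score <= 0:
            continue
        ev = estimate_evalue(aln.score, len(seqs[a]), len(seqs[b]),
                             calibration, database_size=database_size)
        cov_a = (aln.query_span[1] - aln.query_span[0]) / len(seqs[a])
        cov_b = (aln.subject_span[1] - aln.subject_span[0]) / len(seqs[b])
        hits.append(SimilarityHit(a, b, aln.score, ev, cov_a, aln.percent_identity, cov_b))
        hits.append(SimilarityHit(b, a, aln.score, ev, cov_b, aln.percent_identity, cov_a))
    return hits


def read_blast_tab(path: str | Path, lengths: Mapping[str, int]) -> list[SimilarityHit]:
    """Adapter for precomputed tabular (outfmt-6-like) search output.

    Columns: query, subject, identity, alnlen, qstart, qend, sstart, send,
    evalue, bitscore (1-based inclusive coordinates, the BLAST convention).
    Coverage is computed from the aligned spans and the supplied sequence
    lengths.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            q, s, pid, _alnlen, qs, qe, ss, se, ev, bits = line.split("\t")[:10]
            qcov = (int(qe) - int(qs) + 1) / lengths[q]
            scov = (int(se) - int(ss) + 1) / lengths[s]
            hits.append(
                SimilarityHit(q, s, float(bits), float(ev), qcov, float(pid), scov)
            )
    return hits


# ---------------------------------------------------------------------------
# filtering and BDBH graph


def filter_hits(hits: Iterable[SimilarityHit], config: HitFilterConfig | None = None) -> list[SimilarityHit]:
    """Apply coverage / E-value / identity thresholds; drop self-hits.

    Order is preserved and the operation is idempotent.
    """
    config = config or HitFilterConfig()
    kept = []
    for hit in hits:
        if hit.query == hit.subject:
            continue
        if hit.evalue > config.max_evalue:
            continue
        if hit.query_coverage < config.min_coverage:
            continue
        if (
            config.require_both_coverage
            and hit.subject_coverage is not None
            and hit.subject_coverage < config.min_coverage
        ):
            continue
        if hit.percent_identity < config.min_identity:
            continue
        kept.append(hit)
    return kept


def _best_hits(
    hits: Sequence[SimilarityHit], protein_genome: Mapping[str, str]
) -> dict[tuple[str, str], SimilarityHit]:
    """Best hit of each protein into each genome.

    Best = highest score, ties broken by lower E-value then lexicographic
    subject id.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for hit in hits:
        for pid in (hit.query, hit.subject):
            if pid not in protein_genome:
                raise ValueError(f"protein {pid} has no known genome")
        key = (hit.query, protein_genome[hit.subject])
        cur = best.get(key)
        if cur is None or (-hit.score, hit.evalue, hit.subject) < (-cur.score, cur.evalue, cur.subject):
            best[key] = hit
    return best


def build_bdbh_graph(
    hits: Sequence[SimilarityHit], protein_genome: Mapping[str, str]
) -> nx.Graph:
    """Reciprocal-best-hit graph over proteins.

    An undirected edge (a, b) exists iff a is b's best hit in a's genome and
    vice versa; this applies between genomes and, for paralog support,
    within a genome (self-hits having been removed upstream).  Edge weight
    is -log10(max(E, 1e-180)).
    """
    best = _best_hits(hits, protein_genome)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(protein_genome))
    for (query, sgenome), hit in sorted(best.items()):
        reciprocal = best.get((hit.subject, protein_genome[query]))
        if reciprocal is not None and reciprocal.subject == query:
            weight = -np.log10(max(hit.evalue, EVALUE_FLOOR))
            graph.add_edge(hit.query, hit.subject, weight=float(weight))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering


def _mcl_matrix(m: np.ndarray, config: MclConfig) -> tuple[np.ndarray, bool]:
    """Run the MCL iteration on a dense column-stochastic matrix."""
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(config.max_iterations):
        expanded = np.linalg.matrix_power(m, config.expansion)
        inflated = expanded ** config.inflation
        inflated[inflated < config.prune_threshold] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < config.convergence_tol:
            m = inflated
            converged = True
            break
        m = inflated
    return m, converged


def _interpret_mcl(m: np.ndarray, nodes: list[str]) -> list[list[str]]:
    """Read clusters from a converged MCL matrix.

    Attractors are nodes with positive diagonal mass; each attractor's row
    support is a cluster.  Overlapping or unassigned nodes are resolved
    deterministically: larger cluster wins, ties go to the cluster whose
    smallest member id sorts first; leftovers become singletons.
    """
    eps = 1e-8
    raw: list[set[int]] = []
    for i in range(len(nodes)):
        if m[i, i] > eps:
            raw.append({j for j in range(len(nodes)) if m[i, j] > eps})
    # merge identical / overlapping attractor systems
    merged: list[set[int]] = []
    for cluster in raw:
        for existing in merged:
            if cluster & existing:
                existing |= cluster
                break
        else:
            merged.append(set(cluster))
    assigned: dict[int, int] = {}
    order = sorted(
        range(len(merged)),
        key=lambda ci: (-len(merged[ci]), min(nodes[j] for j in merged[ci])),
    )
    for ci in order:
        for j in merged[ci]:
            assigned.setdefault(j, ci)
    clusters: dict[int, list[str]] = defaultdict(list)
    for j, ci in assigned.items():
        clusters[ci].append(nodes[j])
    out = [sorted(members) for members in clusters.values()]
    for j in range(len(nodes)):
        if j not in assigned:
            out.append([nodes[j]])
    return sorted(out, key=lambda c: c[0])


def mcl_cluster(
    graph: nx.Graph,
    config: MclConfig | None = None,
    protein_genome: Mapping[str, str] | None = None,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[OrthologCluster]:
    """Markov clustering of the BDBH graph into ortholog clusters.

    Each connected component is clustered independently (transition
    probability across components is zero, so this is exact).  Every node
    ends up in exactly one cluster; the representative is the longest
    member sequence when lengths are supplied, ties and the no-length case
    falling back to the lexicographically smallest id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    config = config or MclConfig()
    member_lists: list[list[str]] = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            member_lists.append(nodes)
            continue
        sub = graph.subgraph(nodes)
        m = np.zeros((len(nodes), len(nodes)))
        idx = {n: i for i, n in enumerate(nodes)}
        for a, b, data in sub.edges(data=True):
            w = float(data.get("weight", 1.0))
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
        if config.self_loops:
            loop = m.max(axis=0)
            loop[loop == 0] = 1.0
            np.fill_diagonal(m, loop)
        m, converged = _mcl_matrix(m, config)
        if not converged:
            warnings.warn(
                f"MCL did not converge in {config.max_iterations} iterations; "
                "interpreting current matrix",
                RuntimeWarning,
            )
        member_lists.extend(_interpret_mcl(m, nodes))

    member_lists.sort(key=lambda c: c[0])
    clusters = []
    for i, members in enumerate(member_lists, start=1):
        if seq_lengths:
            rep = min(members, key=lambda p: (-seq_lengths.get(p, 0), p))
        else:
            rep = min(members)
        genome_of = protein_genome or {}
        clusters.append(
            OrthologCluster(
                cluster_id=f"C{i:06d}",
                members=tuple((genome_of.get(p, p.split("|")[0]), p) for p in members),
                representative=rep,
            )
        )
    return clusters


def cluster_proteomes(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    filter_config: HitFilterConfig | None = None,
    mcl_config: MclConfig | None = None,
    calibration: EValueCalibration | None = None,
) -> list[OrthologCluster]:
    """End-to-end orthology: search, filter, BDBH graph, MCL."""
    protein_genome = {
        pid: genome for genome, plist in proteomes.items() for pid, _ in plist
    }
    seq_lengths = {
        pid: len(seq) for plist in proteomes.values() for pid, seq in plist
    }
    hits = all_vs_all_hits(proteomes, calibration=calibration)
    kept = filter_hits(hits, filter_config)
    graph = build_bdbh_graph(kept, protein_genome)
    return mcl_cluster(graph, mcl_config, protein_genome, seq_lengths)


def write_clusters(clusters: Sequence[OrthologCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cluster in clusters:
            members = ",".join(cluster.protein_ids)
            fh.write(f"{cluster.cluster_id}\t{cluster.representative}\t{members}\n")
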
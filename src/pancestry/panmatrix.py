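"""The family-by-genome count matrix and its occupancy partition.

The pan-matrix is the central object of a pangenome analysis: rows are
gene families (ortholog clusters), columns are genomes, and cells count
family members.  Families are partitioned by occupancy (number of genomes
with at least one member) into:

* core      - present in every genome,
* softcore  - present in >= ceil(0.95 * G) genomes (includes core),
* cloud     - occupancy at most M + 1, where M is the modal occupancy among
              non-softcore families (smallest mode on ties),
* shell     - everything in between.

The strict core keeps only core families with exactly one member per
genome - true single-copy orthologs, the input to core-gene trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import OrthologCluster


@dataclass(frozen=True)
class QcRecord:
    genome_id: str
    completeness: float  # percent
    contamination: float  # percent

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


def read_qc_table(path: str | Path) -> list[QcRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        QcRecord(str(r.genome_id), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    ]


def qc_filter_genomes(
    records: Sequence[QcRecord],
    min_completeness: float = 99.0,
    max_contamination: float = 5.0,
    force_include: Iterable[str] = (),
) -> list[str]:
    """Genome ids with completeness > threshold AND contamination < threshold.

    ``force_include`` ids are retained regardless (the escape hatch for
    taxa needed to complete a phylogeny despite failing QC).  Thresholds
    are strict inequalities.
    """
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in QC table")
    force = set(force_include)
    kept = [
        r.genome_id
        for r in records
        if (r.completeness > min_completeness and r.contamination < max_contamination)
        or r.genome_id in force
    ]
    return kept


class PanMatrix:
    """Family x genome integer count matrix (a thin pandas wrapper)."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if counts.shape[0] and (counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero family rows are not allowed")
        self.counts = counts.astype(int)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    def occupancy(self) -> pd.Series:
        """Number of genomes holding at least one member, per family."""
        return (self.counts > 0).sum(axis=1)

    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    def drop_genomes(self, genomes: Iterable[str]) -> "PanMatrix":
        keep = [g for g in self.genome_ids if g not in set(genomes)]
        sub = self.counts[keep]
        return PanMatrix(sub[sub.sum(axis=1) > 0])

    # -- text formats ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="family_id"))

    def to_phylip_presence(self, path: str | Path) -> None:
        """Relaxed-PHYLIP binary presence matrix (genomes as rows)."""
        pres = self.presence().T  # genomes x families
        with open(path, "w") as fh:
            fh.write(f"{pres.shape[0]} {pres.shape[1]}\n")
            for genome, row in pres.iterrows():
                fh.write(f"{genome}  {''.join(map(str, row.values))}\n")

    def __eq__(self, other) -> bool:
        return isinstance(other, PanMatrix) and self.counts.equals(other.counts)


def build_pan_matrix(
    clusters: Sequence[OrthologCluster], genome_ids: Sequence[str]
) -> PanMatrix:
    """Count cluster members per genome; clusters with no member in the
    listed genomes are dropped (no all-zero rows)."""
    genome_set = set(genome_ids)
    fam_ids = [c.cluster_id for c in clusters]
    counts = pd.DataFrame(0, index=fam_ids, columns=list(genome_ids), dtype=int)
    for cluster in clusters:
        for genome, _pid in cluster.members:
            if genome not in genome_set:
                raise ValueError(f"cluster member from unknown genome {genome}")
            counts.loc[cluster.cluster_id, genome] += 1
    counts = counts[counts.sum(axis=1) > 0]
    return PanMatrix(counts)


def pan_matrix_from_presence(
    node_families: Mapping[str, Iterable[str]], genome_ids: Sequence[str]
) -> PanMatrix:
    """Pan-matrix (single copy) straight from a family-presence mapping."""
    families = sorted({f for g in genome_ids for f in node_families[g]})
    counts = pd.DataFrame(0, index=families, columns=list(genome_ids), dtype=int)
    for genome in genome_ids:
        for fam in node_families[genome]:
            counts.loc[fam, genome] = 1
    return PanMatrix(counts[counts.sum(axis=1) > 0])


@dataclass(frozen=True)
class OccupancyPartition:
    """Disjoint core / softcore-only / shell / cloud family sets.

    ``softcore`` here is the softcore-only set (softcore minus core); use
    ``softcore_total`` for the conventional superset count that includes
    the core.
    """

    core: frozenset[str]
    softcore: frozenset[str]
    shell: frozenset[str]
    cloud: frozenset[str]
    softcore_threshold: int
    cloud_threshold: int

    @property
    def softcore_total(self) -> frozenset[str]:
        return self.core | self.softcore

    def class_of(self, family_id: str) -> str:
        for name in ("core", "softcore", "shell", "cloud"):
            if family_id in getattr(self, name):
                return name
        raise KeyError(family_id)


def partition_occupancy(
    matrix: PanMatrix, softcore_fraction: float = 0.95, cloud_offset: int = 1
) -> OccupancyPartition:
    """Partition families by occupancy.

    Core = occupancy G; softcore = occupancy >= ceil(softcore_fraction*G).
    Among non-softcore families, M is the modal occupancy (smallest on
    ties) and cloud = occupancy <= M + cloud_offset; shell is the rest.
    """
    G = matrix.n_genomes
    if G < 2:
        raise ValueError("need at least 2 genomes")
    if matrix.counts.shape[0] == 0:
        raise ValueError("empty pan-matrix")
    occ = matrix.occupancy()
    softcore_threshold = math.ceil(softcore_fraction * G)
    core = frozenset(occ.index[occ == G])
    softcore_all = frozenset(occ.index[occ >= softcore_threshold])
    softcore_only = softcore_all - core
    rest = occ[~occ.index.isin(softcore_all)]
    if len(rest) == 0:
        cloud_threshold = 0
        cloud: frozenset[str] = frozenset()
        shell: frozenset[str] = frozenset()
    else:
        counts = rest.value_counts()
        max_count = counts.max()
        modal = min(int(v) for v, c in counts.items() if c == max_count)
        cloud_threshold = modal + cloud_offset
        cloud = frozenset(rest.index[rest <= cloud_threshold])
        shell = frozenset(rest.index) - cloud
    return OccupancyPartition(
        core, softcore_only, shell, cloud, softcore_threshold, cloud_threshold
    )


@dataclass(frozen=True)
class StrictCore:
    family_ids: frozenset[str]


def extract_strict_core(matrix: PanMatrix, partition: OccupancyPartition) -> StrictCore:
    """Core families with exactly one member per genome (paralogs removed)."""
    core = sorted(partition.core)
    if not core:
        return StrictCore(frozenset())
    sub = matrix.counts.loc[core]
    strict = sub.index[(sub == 1).all(axis=1)]
    return StrictCore(frozenset(strict))


def write_partition_report(
    matrix: PanMatrix, partition: OccupancyPartition, path: str | Path
) -> None:
    occ = matrix.occupancy()
    with open(path, "w") as fh:
        fh.write("family_id\toccupancy\tclass\n")
        for fam in matrix.family_ids:
            fh.write(f"{fam}\t{occ[fam]}\t{partition.class_of(fam)}\n")
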
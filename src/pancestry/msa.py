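"""A deterministic progressive multiple aligner for desk-scale protein sets.

Guide order comes from k-mer profile distances clustered with UPGMA;
profiles are then merged pairwise with an affine-gap global (Gotoh)
profile-profile alignment scored by expected BLOSUM62 sum-of-pairs.  This
is a self-contained aligner in the MUSCLE/CLUSTAL mould, adequate for the
moderately diverged single-copy families a core-gene tree consumes; an
externally computed alignment can be substituted wherever an Alignment is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .simulate import AMINO_ACIDS

GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _blosum_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a][b]
    return m


_BLOSUM = _blosum_matrix()


@dataclass
class Alignment:
    """Aligned sequences of equal length with optional per-column source ids."""

    ids: list[str]
    seqs: list[str]
    column_sources: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("taxon ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if self.column_sources is not None and self.seqs:
            if len(self.column_sources) != len(self.seqs[0]):
                raise ValueError("column_sources length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sum_of_pairs_score(self, open_penalty: float = 11.0, extend_penalty: float = 1.0) -> float:
        """Sum over sequence pairs of BLOSUM62 column scores minus affine gap costs."""
        total = 0.0
        for i in range(len(self.seqs)):
            for j in range(i + 1, len(self.seqs)):
                total += _pairwise_sp(self.seqs[i], self.seqs[j], open_penalty, extend_penalty)
        return total


def _pairwise_sp(a: str, b: str, open_p: float, ext_p: float) -> float:
    score = 0.0
    gap_run = 0  # 0 none, 1 gap in a, 2 gap in b
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        if ca == GAP or cb == GAP:
            state = 1 if ca == GAP else 2
            score -= open_p if gap_run != state else ext_p
            gap_run = state
        else:
            score += _BLOSUM[_AA_INDEX[ca], _AA_INDEX[cb]]
            gap_run = 0
    return score


def _profile(aln: Alignment) -> np.ndarray:
    """Residue frequency matrix (columns x 20); gaps carry zero weight."""
    prof = np.zeros((aln.n_columns, 20))
    for seq in aln.seqs:
        for c, ch in enumerate(seq):
            if ch != GAP:
                prof[c, _AA_INDEX[ch]] += 1
    return prof / len(aln.seqs)


def _align_profiles(
    a: Alignment, b: Alignment, open_p: float, ext_p: float
) -> Alignment:
    """Global affine-gap alignment of two profiles (row-vectorized Gotoh)."""
    pa, pb = _profile(a), _profile(b)
    La, Lb = pa.shape[0], pb.shape[0]
    C = pa @ _BLOSUM @ pb.T  # column-vs-column expected score
    NEG = -1e30

    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap columns inserted into b
    Y = np.full((La + 1, Lb + 1), NEG)  # gap columns inserted into a
    M[0, 0] = 0.0
    j = np.arange(1, Lb + 1)
    for i in range(La + 1):
        if i > 0:
            best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
            M[i, 1:] = C[i - 1, :] + best_prev[:-1]
            M[i, 0] = NEG
            X[i] = np.maximum(M[i - 1] - open_p, X[i - 1] - ext_p)
        # Y within the row: Y[i,j] = max_{k<=j-1} M[i,k] - open - (j-1-k)*ext
        B = M[i] + np.arange(Lb + 1) * ext_p
        running = np.maximum.accumulate(B)
        Y[i, 1:] = running[:-1] - open_p - (j - 1) * ext_p

    # traceback
    cols: list[tuple[int, int]] = []  # (-1 for gap, source column index)
    i_, j_ = La, Lb
    state = int(np.argmax([M[i_, j_], X[i_, j_], Y[i_, j_]]))
    tol = 1e-6
    while i_ > 0 or j_ > 0:
        if state == 0:
            cols.append((i_ - 1, j_ - 1))
            i_, j_ = i_ - 1, j_ - 1
            state = int(np.argmax([M[i_, j_], X[i_, j_], Y[i_, j_]]))
        elif state == 1:
            cols.append((i_ - 1, -1))
            if abs(X[i_, j_] - (X[i_ - 1, j_] - ext_p)) < tol:
                state = 1
            else:
                state = 0
            i_ -= 1
        else:
            cols.append((-1, j_ - 1))
            if abs(Y[i_, j_] - (Y[i_, j_ - 1] - ext_p)) < tol:
                state = 2
            else:
                state = 0
            j_ -= 1
    cols.reverse()

    def expand(seqs: list[str], which: int) -> list[str]:
        out = []
        for seq in seqs:
            chars = []
            for ca, cb in cols:
                idx = ca if which == 0 else cb
                chars.append(GAP if idx < 0 else seq[idx])
            out.append("".join(chars))
        return out

    sources = None
    if a.column_sources is not None and b.column_sources is not None:
        sources = [
            a.column_sources[ca] if ca >= 0 else b.column_sources[cb]
            for ca, cb in cols
        ]
    return Alignment(a.ids + b.ids, expand(a.seqs, 0) + expand(b.seqs, 1), sources)


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """Fraction-of-shared-k-mers distance matrix (condensed form)."""
    profiles = []
    for seq in seqs:
        counts: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        profiles.append(counts)
    n = len(seqs)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(
                min(c, profiles[j].get(kmer, 0)) for kmer, c in profiles[i].items()
            )
            denom = max(1, min(len(seqs[i]), len(seqs[j])) - k + 1)
            out.append(1.0 - shared / denom)
    return np.array(out)


def progressive_align(
    sequences: Sequence[tuple[str, str]],
    cluster_id: str | None = None,
    open_penalty: float = 11.0,
    extend_penalty: float = 1.0,
) -> Alignment:
    """Progressively align ``(id, sequence)`` pairs.

    A single sequence is returned unchanged.  The merge order follows a
    UPGMA guide tree on k-mer distances; ties resolve deterministically
    through scipy's linkage ordering on the (sorted-input) matrix.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    sequences = sorted(sequences)
    source = [cluster_id] if cluster_id is not None else None

    def leaf(sid: str, seq: str) -> Alignment:
        src = [cluster_id] * len(seq) if cluster_id is not None else None
        return Alignment([sid], [seq], src)

    if len(sequences) == 1:
        return leaf(*sequences[0])
    if len(sequences) == 2:
        return _align_profiles(
            leaf(*sequences[0]), leaf(*sequences[1]), open_penalty, extend_penalty
        )

    dm = _kmer_distance([s for _, s in sequences])
    merges = linkage(dm, method="average")
    nodes: dict[int, Alignment] = {
        i: leaf(sid, seq) for i, (sid, seq) in enumerate(sequences)
    }
    n = len(sequences)
    for step, (left, right, _dist, _count) in enumerate(merges):
        nodes[n + step] = _align_profiles(
            nodes[int(left)], nodes[int(right)], open_penalty, extend_penalty
        )
    return nodes[n + len(merges) - 1]
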
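"""Protein local alignment and an extreme-value E-value surrogate.

Pairwise scoring uses Smith-Waterman/Gotoh with BLOSUM62 and affine gaps
(Biopython's C PairwiseAligner).  Significance is assigned through a
Karlin-Altschul style E-value, E = K*m*n*exp(-lambda*S), with (lambda, K)
calibrated once per scoring scheme from a Gumbel fit to scores of random
decoy alignments.  The coverage/E-value decision thresholds downstream are
therefore the same contract a BLAST-based pipeline would apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .simulate import AMINO_ACIDS

_VALID = set(AMINO_ACIDS)


class InvalidResidueError(ValueError):
    pass


class UncalibratedSchemeError(RuntimeError):
    pass


def make_aligner(open_penalty: float = 11.0, extend_penalty: float = 1.0,
                 matrix: str = "BLOSUM62", mode: str = "local") -> Align.PairwiseAligner:
    """Affine-gap aligner; a gap of length k costs open + (k-1)*extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_penalty
    aligner.extend_gap_score = -extend_penalty
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_span: tuple[int, int]  # half-open residue interval on the query
    subject_span: tuple[int, int]
    percent_identity: float  # over aligned columns, gaps excluded
    aligned_columns: int


def _check(seq: str, name: str) -> None:
    if not seq:
        raise InvalidResidueError(f"{name} is empty")
    bad = set(seq) - _VALID
    if bad:
        raise InvalidResidueError(f"{name} contains invalid residues: {sorted(bad)}")


def local_align_score(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> LocalAlignment:
    """Optimal local alignment score, spans, and percent identity.

    If no positive-scoring local alignment exists the score floors at 0
    with empty spans (the Smith-Waterman convention).
    """
    _check(seq_a, "query")
    _check(seq_b, "subject")
    aligner = aligner or make_aligner()
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0.0, 0)
    aln = next(iter(aligner.align(seq_a, seq_b)))
    qblocks, sblocks = aln.aligned
    ident = 0
    ncols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for qa, sb in zip(seq_a[qs:qe], seq_b[ss:se]):
            ncols += 1
            if qa == sb:
                ident += 1
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    pid = 100.0 * ident / ncols if ncols else 0.0
    return LocalAlignment(float(score), qspan, sspan, pid, ncols)


@dataclass(frozen=True)
class EValueCalibration:
    """Gumbel parameters of the null score distribution for one scheme.

    For random sequences of lengths m0 x n0 the maximal local score follows
    a Gumbel law with location ln(K*m0*n0)/lambda and scale 1/lambda.
    """

    lam: float
    K: float
    length: int
    n_pairs: int


def calibrate_evalue(
    aligner: Align.PairwiseAligner | None = None,
    n_pairs: int = 300,
    length: int = 120,
    seed: int = 1729,
) -> EValueCalibration:
    """Fit (lambda, K) from local scores of random decoy sequence pairs."""
    from scipy.stats import gumbel_r

    aligner = aligner or make_aligner()
    rng = np.random.default_rng(seed)
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        a = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))
        b = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))
        scores[i] = aligner.score(a, b)
    loc, scale = gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (length * length)
    return EValueCalibration(lam=lam, K=K, length=length, n_pairs=n_pairs)


def estimate_evalue(
    score: float,
    query_len: int,
    subject_len: int,
    calibration: EValueCalibration | None,
    database_size: int | None = None,
) -> float:
    """E = K * m * n' * exp(-lambda * score).

    ``n'`` is the total database residue count when given (the search-space
    convention), otherwise the subject length (pairwise convention).
    """
    if calibration is None:
        raise UncalibratedSchemeError("no E-value calibration for this scoring scheme")
    n_eff = database_size if database_size is not None else subject_len
    return calibration.K * query_len * n_eff * math.exp(-calibration.lam * score)
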
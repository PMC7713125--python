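"""Genome-sampling pan/core size curves and Tettelin exponential fits.

Random genome orderings yield, at each sample size n, the pan-genome size
(union of families), the core size (intersection), and the number of
families new to the union.  Each mean curve is fitted with the Tettelin
three-parameter exponential

    F(n) = kappa * exp(-n / tau) + offset,

where the offset is the asymptote: Omega, the stable core size, for the
core curve, and tg(theta), the asymptotic number of new genes contributed
per additional genome, for the new-genes curve.  A pangenome is called
open when tg(theta) stays above a small epsilon - every added genome keeps
bringing new families.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .panmatrix import PanMatrix

CurveKind = Literal["pan", "core", "new-genes"]


@dataclass(frozen=True)
class SamplingCurve:
    kind: CurveKind
    n: np.ndarray  # genome counts 1..G
    mean_size: np.ndarray
    sd_size: np.ndarray
    n_permutations: int

    def __post_init__(self) -> None:
        if not (len(self.n) == len(self.mean_size) == len(self.sd_size)):
            raise ValueError("curve arrays must have equal length")
        if (self.sd_size < 0).any():
            raise ValueError("sd must be >= 0")


def sample_size_curves(
    matrix: PanMatrix, n_permutations: int = 10, seed: int | None = 0
) -> tuple[SamplingCurve, SamplingCurve, SamplingCurve]:
    """Pan, core and new-genes curves over random genome orderings.

    When ``n_permutations`` covers all G! orderings the exhaustive set is
    used instead of sampling, making small-G results exact.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if matrix.counts.shape[0] == 0:
        raise ValueError("empty pan-matrix")
    presence = matrix.presence().values.astype(bool)  # families x genomes
    G = presence.shape[1]

    if math.factorial(G) <= n_permutations:
        orderings = [list(p) for p in itertools.permutations(range(G))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [list(rng.permutation(G)) for _ in range(n_permutations)]

    pan = np.empty((len(orderings), G))
    core = np.empty((len(orderings), G))
    new = np.empty((len(orderings), G))
    for i, order in enumerate(orderings):
        union = np.zeros(presence.shape[0], dtype=bool)
        inter = np.ones(presence.shape[0], dtype=bool)
        prev_union = 0
        for k, g in enumerate(order):
            union |= presence[:, g]
            inter &= presence[:, g]
            pan[i, k] = union.sum()
            core[i, k] = inter.sum()
            new[i, k] = pan[i, k] - prev_union
            prev_union = pan[i, k]

    n = np.arange(1, G + 1)

    def curve(kind: CurveKind, data: np.ndarray) -> SamplingCurve:
        return SamplingCurve(kind, n, data.mean(axis=0), data.std(axis=0), len(orderings))

    return curve("pan", pan), curve("core", core), curve("new-genes", new)


@dataclass(frozen=True)
class TettelinFit:
    kappa: float
    tau: float
    offset: float  # Omega for core; tg(theta) for pan / new-genes
    rss: float
    converged: bool
    saturation_n: int | None  # smallest n with kappa*exp(-n/tau) < 1% of kappa
    kind: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def fit_tettelin(curve: SamplingCurve) -> TettelinFit:
    """Bounded multi-start nonlinear least squares for the exponential model.

    The model is ill-conditioned for near-flat curves, so tau is started
    from a log-spaced grid within [0.1, 10*G] and (kappa, offset) are
    profiled linearly at each start.  A constant curve short-circuits to
    kappa ~ 0 with offset equal to the constant.
    """
    if len(curve.n) < 4:
        raise ValueError("need at least 4 curve points to fit")
    n = np.asarray(curve.n, dtype=float)
    y = np.asarray(curve.mean_size, dtype=float)
    G = n.max()

    if np.ptp(y) < 1e-9:
        return TettelinFit(0.0, 1.0, float(y[0]), 0.0, True, None, curve.kind)

    lo, hi = 0.1, 10.0 * G

    def residuals(theta: np.ndarray) -> np.ndarray:
        kappa, tau, offset = theta
        return kappa * np.exp(-n / tau) + offset - y

    best = None
    for tau0 in np.geomspace(lo, hi, 12):
        basis = np.exp(-n / tau0)
        A = np.column_stack([basis, np.ones_like(n)])
        (k0, c0), *_ = np.linalg.lstsq(A, y, rcond=None)
        try:
            res = least_squares(
                residuals,
                x0=[k0, tau0, c0],
                bounds=([-np.inf, lo, -np.inf], [np.inf, hi, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return TettelinFit(math.nan, math.nan, math.nan, math.inf, False, None, curve.kind)

    kappa, tau, offset = (float(v) for v in best.x)
    rss = float(2 * best.cost)
    saturation = int(math.ceil(tau * math.log(100.0))) if abs(kappa) > 1e-9 else None
    return TettelinFit(kappa, tau, offset, rss, bool(best.success), saturation, curve.kind)


class NotConvergedError(RuntimeError):
    pass


def classify_openness(
    new_genes_fit: TettelinFit, epsilon: float = 1.0
) -> tuple[Literal["open", "closed"], float]:
    """Open iff the asymptotic new-genes-per-genome tg(theta) exceeds epsilon."""
    if not new_genes_fit.converged:
        raise NotConvergedError("cannot classify openness from a non-converged fit")
    label: Literal["open", "closed"] = "open" if new_genes_fit.offset > epsilon else "closed"
    return label, new_genes_fit.offset


def write_curves_tsv(curves: tuple[SamplingCurve, ...], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tn\tmean\tsd\n")
        for curve in curves:
            for n, m, s in zip(curve.n, curve.mean_size, curve.sd_size):
                fh.write(f"{curve.kind}\t{n}\t{m:.6g}\t{s:.6g}\n")
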
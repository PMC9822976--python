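"""Average conditional exceedance rate (ACER) estimation.

For the pooled vector R with unified limits eta and a scaling parameter
lambda lowering every limit at once, the conditional exceedance probability
at conditioning level k is

    p_k(lambda) = Prob{ R_j > eta_j*lambda |
                        R_{j-1} <= eta_{j-1}*lambda, ...,
                        R_{j-k+1} <= eta_{j-k+1}*lambda },

estimated empirically as the count of indices j (k <= j <= N) where the
exceedance occurs jointly with the k-1 preceding non-exceedances, divided by
N - k + 1, the number of indices where the k-step condition is definable.
This average joint-event rate is the standard ACER estimator; it coincides
with the conditional probability in the tail, where the conditioning event
holds almost surely.  k = 1 is the plain exceedance fraction (the discrete
counterpart of the mean up-crossing rate); larger k absorbs clustering of
exceedances among neighbouring pooled maxima.  The system non-exceedance
probability follows the Poisson-type relation P_k(lambda) ~ exp(-N p_k).

A binomial-style approximate confidence band is

    CI+-(lambda) = p_k (1 +- f(p) / sqrt((N - k + 1) p_k)),

with f the two-sided standard-normal multiplier of the confidence level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import DomainError
from .merge import MergedVector

log = logging.getLogger(__name__)

__all__ = [
    "AcerCurve",
    "ConfidenceBand",
    "ConvergenceResult",
    "make_grid",
    "default_grid",
    "empirical_pk",
    "convergence_in_k",
    "nonexceedance_probability",
    "mixture_pk",
    "normal_multiplier",
    "confidence_band",
]


def make_grid(levels: Sequence[float]) -> np.ndarray:
    """Validate a lambda grid: strictly increasing, positive."""
    grid = np.asarray(levels, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise DomainError("lambda grid must be a non-empty 1-D array")
    if np.any(grid <= 0):
        raise DomainError("lambda levels must be positive")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise DomainError("lambda levels must be strictly increasing")
    return grid


def default_grid(
    merged: MergedVector, n_levels: int = 200, lo_quantile: float = 0.05
) -> np.ndarray:
    """Equally spaced levels from the low quantile of R/eta up to its maximum.

    If the low quantile is non-positive (possible for Gaussian test panels)
    the grid starts at the smallest positive scaled value instead.
    """
    x = merged.scaled
    lo = float(np.quantile(x, lo_quantile))
    hi = float(np.max(x))
    if lo <= 0:
        positive = x[x > 0]
        if len(positive) == 0:
            raise DomainError("no positive scaled values; cannot build a lambda grid")
        lo = float(np.min(positive))
    if not hi > lo:
        raise DomainError("degenerate scaled values; cannot build a lambda grid")
    return make_grid(np.linspace(lo, hi, n_levels))


@dataclass(frozen=True)
class AcerCurve:
    """Empirical p_k on a lambda grid.

    ``p = exceed_counts / n_effective`` with ``n_effective = N - k + 1``;
    for idealised noise-free curves (exact tail forms used as fit-recovery
    truth) p is exact and counts are its rounded expectation.
    """

    lambdas: np.ndarray
    p: np.ndarray
    exceed_counts: np.ndarray
    k: int
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", make_grid(self.lambdas))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(
            self, "exceed_counts", np.asarray(self.exceed_counts, dtype=float)
        )
        if not (len(self.p) == len(self.lambdas) == len(self.exceed_counts)):
            raise DomainError("curve arrays must share the grid length")
        if self.k < 1:
            raise DomainError("conditioning level k must be >= 1")
        if np.any((self.p < 0) | (self.p > 1)):
            raise DomainError("p values must lie in [0, 1]")

    @property
    def n_effective(self) -> int:
        return self.n - self.k + 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "p": self.p,
                "count": self.exceed_counts,
                "n_eff": self.n_effective,
                "k": self.k,
            }
        )


@dataclass(frozen=True)
class ConfidenceBand:
    """Approximate CI-/CI+ curves around p_k; NaN where p_k = 0 (undefined)."""

    lambdas: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    multiplier: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.lower) & ~np.isnan(self.upper)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lambda": self.lambdas, "ci_lo": self.lower, "ci_hi": self.upper}
        )


@dataclass(frozen=True)
class ConvergenceResult:
    """Outcome of the convergence-in-k scan."""

    k_star: int
    curves: dict[int, AcerCurve]
    converged: bool
    max_rel_change: dict[int, float]


def _exceed_counts(x: np.ndarray, k: int, grid: np.ndarray) -> np.ndarray:
    """Count, per level, indices j with x_j > lambda and the k-1 previous <= lambda."""
    n = len(x)
    counts = np.empty(len(grid), dtype=np.int64)
    for g, lam in enumerate(grid):
        exceed = x > lam
        if k == 1:
            counts[g] = int(exceed.sum())
        else:
            event = exceed[k - 1 :].copy()
            for back in range(1, k):
                event &= ~exceed[k - 1 - back : n - back]
            counts[g] = int(event.sum())
    return counts


def empirical_pk(merged: MergedVector, k: int, grid: Sequence[float]) -> AcerCurve:
    """Estimate p_k(lambda) on the given grid from the pooled vector.

    The conditioning runs over the merged sequence as a whole — exceedances
    are screened in pooled time order regardless of source component, which
    is precisely what suppresses cascades of inter-correlated exceedances.
    """
    grid = make_grid(grid)
    n = merged.n
    if k < 1:
        raise DomainError("conditioning level k must be >= 1")
    if k > n:
        raise DomainError(f"conditioning level k={k} exceeds vector length N={n}")
    counts = _exceed_counts(merged.scaled, k, grid)
    n_eff = n - k + 1
    return AcerCurve(
        lambdas=grid, p=counts / n_eff, exceed_counts=counts, k=k, n=n
    )


def nonexceedance_probability(curve: AcerCurve) -> np.ndarray:
    """System non-exceedance P_k(lambda) ~ exp(-N p_k(lambda))."""
    return np.exp(-curve.n * curve.p)


def convergence_in_k(
    merged: MergedVector,
    grid: Sequence[float],
    k_max: int = 4,
    tol: float = 0.05,
    tail_from: float | None = None,
    min_count: int = 10,
) -> ConvergenceResult:
    """Scan k = 1..k_max and pick the smallest k with a settled tail.

    k* is the smallest k whose curve differs from the k+1 curve by at most
    ``tol`` relative, taken over the tail region (levels >= ``tail_from``,
    by default the upper half of the grid) where both curves rest on at
    least ``min_count`` observed exceedances — sparser levels carry
    sampling noise that never settles, regardless of k.  If no k
    converges, k_max is returned with ``converged=False`` and a warning —
    never silently.
    """
    if k_max < 2:
        raise DomainError("k_max must be >= 2 to assess convergence")
    grid = make_grid(grid)
    curves = {k: empirical_pk(merged, k, grid) for k in range(1, k_max + 1)}
    if tail_from is None:
        tail_from = float(grid[len(grid) // 2])
    region = grid >= tail_from

    max_change: dict[int, float] = {}
    k_star, converged = k_max, False
    for k in range(1, k_max):
        a, b = curves[k].p, curves[k + 1].p
        mask = (
            region
            & (curves[k].exceed_counts >= min_count)
            & (curves[k + 1].exceed_counts >= min_count)
        )
        if not mask.any():
            max_change[k] = np.nan
            continue
        rel = float(np.max(np.abs(a[mask] - b[mask]) / a[mask]))
        max_change[k] = rel
        if rel <= tol and not converged:
            k_star, converged = k, True
    if not converged:
        log.warning(
            "no convergence in k up to k_max=%d (max relative changes: %s)",
            k_max,
            {k: round(v, 4) for k, v in max_change.items()},
        )
    return ConvergenceResult(
        k_star=k_star, curves=curves, converged=converged, max_rel_change=max_change
    )


def mixture_pk(curves: Sequence[AcerCurve], weights: Sequence[float]) -> AcerCurve:
    """Long-term mixture over M environmental states: p = sum_m q_m p(.,m).

    All curves must share grid and k; weights must be a probability vector.
    The effective sample size is the weight-averaged N, rounded.
    """
    q = np.asarray(weights, dtype=float)
    if len(curves) != len(q):
        raise DomainError("one weight per curve is required")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise DomainError("weights must be non-negative and sum to 1")
    base = curves[0]
    for c in curves[1:]:
        if c.k != base.k or len(c.lambdas) != len(base.lambdas) or not np.allclose(
            c.lambdas, base.lambdas
        ):
            raise DomainError("mixture curves must share the lambda grid and k")
    p = sum(qm * c.p for qm, c in zip(q, curves))
    n_eff_mix = int(round(sum(qm * c.n for qm, c in zip(q, curves))))
    counts = np.round(p * (n_eff_mix - base.k + 1))
    return AcerCurve(
        lambdas=base.lambdas, p=p, exceed_counts=counts, k=base.k, n=n_eff_mix
    )


def normal_multiplier(p_conf: float) -> float:
    """Two-sided standard-normal multiplier: the (1 + p)/2 quantile.

    f(0.95) = 1.96; f(0.90) = 1.645.
    """
    if not 0 < p_conf < 1:
        raise DomainError("confidence level must lie strictly between 0 and 1")
    return float(norm.ppf((1 + p_conf) / 2))


def confidence_band(curve: AcerCurve, p_conf: float = 0.95) -> ConfidenceBand:
    """Approximate confidence band p (1 +- f / sqrt((N-k+1) p)).

    The lower limit is clipped at 0; levels with p = 0 are marked undefined
    (NaN) rather than raising.
    """
    f = normal_multiplier(p_conf)
    p = curve.p
    with np.errstate(divide="ignore", invalid="ignore"):
        half = f / np.sqrt(curve.n_effective * p)
        lower = np.where(p > 0, np.clip(p * (1 - half), 0.0, None), np.nan)
        upper = np.where(p > 0, p * (1 + half), np.nan)
    return ConfidenceBand(
        lambdas=curve.lambdas, lower=lower, upper=upper, level=p_conf, multiplier=f
    )
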
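"""Seeded synthetic panels with the statistical structure the method assumes.

Three generators:

* :func:`gen_gaussian_mdof` — a stationary Gaussian panel: each component is
  an AR(1) process, cross-correlated at lag 0 through a single common
  latent factor (equicorrelation).  This realises the ergodic/stationary
  multi-component setting in its cleanest form and admits closed-form
  checks (AR(1) autocorrelation, normal tail quantiles).
* :func:`gen_cancer_like_panel` — a mortality-like panel: ~195 country
  columns of annual death rates (per cent of local population) over a
  30-year span, built as baseline x (1 + slow linear trend) x
  exp(correlated Gaussian noise).  The log-normal noise keeps rates
  positive; cross-country correlation again enters through a common
  factor.
* :func:`gen_exact_tail_curve` — a noise-free curve following the
  four-parameter tail form exactly, the ground truth for fit-recovery
  tests.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .exceedance import AcerCurve, make_grid
from .panel import MortalityPanel, ScaledPanel

__all__ = [
    "GaussianPanelSpec",
    "CancerPanelSpec",
    "gen_gaussian_mdof",
    "gen_cancer_like_panel",
    "gen_exact_tail_curve",
]


@dataclass(frozen=True)
class GaussianPanelSpec:
    """Stationary AR(1) panel with common-factor cross-correlation.

    ``ar_coefficient`` is the lag-1 autocorrelation phi of every component;
    ``cross_correlation`` rho is the lag-0 correlation between any two
    components, produced by a shared latent factor.
    """

    n_components: int = 10
    n_steps: int = 500
    ar_coefficient: float = 0.0
    cross_correlation: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise DomainError("ar_coefficient must lie in [0, 1)")
        if not 0 <= self.cross_correlation < 1:
            raise DomainError("cross_correlation must lie in [0, 1)")
        if self.n_components < 1 or self.n_steps < 1:
            raise DomainError("panel dimensions must be positive")
        if self.sd <= 0:
            raise DomainError("marginal sd must be positive")


def gen_gaussian_mdof(spec: GaussianPanelSpec) -> ScaledPanel:
    """Generate the Gaussian MDOF panel described by ``spec``.

    Innovations e_t = sqrt(rho) f_t + sqrt(1-rho) z_t share the factor f_t
    across components; each column follows
    x_t = phi x_{t-1} + sqrt(1-phi^2) e_t from a stationary start, so the
    marginal is exactly N(mean, sd^2) at every step.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_components, spec.n_steps
    rho, phi = spec.cross_correlation, spec.ar_coefficient

    factor = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, m))
    innov = np.sqrt(rho) * factor + np.sqrt(1 - rho) * idio

    x = np.empty((n, m))
    x[0] = innov[0]
    scale = np.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + scale * innov[t]

    frame = pd.DataFrame(
        spec.mean + spec.sd * x,
        index=np.arange(n),
        columns=[f"C{i:03d}" for i in range(m)],
    )
    return ScaledPanel(frame=frame)


@dataclass(frozen=True)
class CancerPanelSpec:
    """Mortality-like panel: annual per-country death rates in per cent.

    Defaults emulate the study conditions: 195 countries observed annually
    1990-2019, baseline rates of 0.1-0.3 % of local population, a slow
    upward trend of up to 10 % of baseline across the span, multiplicative
    log-normal noise with sigma = 0.05, and cross-country correlation 0.5
    through a common annual factor.
    """

    n_countries: int = 195
    start_year: int = 1990
    end_year: int = 2019
    baseline_range: tuple[float, float] = (0.1, 0.3)  # per cent of population
    trend_amplitude: float = 0.10  # relative rise over the span
    noise_sd: float = 0.05  # sigma of log-normal multiplicative noise
    cross_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise DomainError("end_year must be >= start_year")
        lo, hi = self.baseline_range
        if lo <= 0 or hi < lo:
            raise DomainError("baseline_range must be positive and ordered")
        if not 0 <= self.cross_correlation < 1:
            raise DomainError("cross_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_countries < 1:
            raise DomainError("n_countries must be positive")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def gen_cancer_like_panel(spec: CancerPanelSpec) -> MortalityPanel:
    """Generate a mortality-like rate panel (value_kind ``rate_percent``).

    rate_{it} = baseline_i * (1 + trend(t)) * exp(sigma * eps_{it}), with
    eps sharing a common annual factor (correlation rho) and trend rising
    linearly from 0 to ``trend_amplitude`` over the span.  Rates are
    truncated at zero (vacuously, as the noise is multiplicative and
    positive).
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_countries, spec.n_years
    lo, hi = spec.baseline_range
    baselines = rng.uniform(lo, hi, size=m)

    rho = spec.cross_correlation
    factor = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, m))
    eps = np.sqrt(rho) * factor + np.sqrt(1 - rho) * idio

    frac = np.linspace(0.0, 1.0, n)[:, None] if n > 1 else np.zeros((1, 1))
    trend = 1.0 + spec.trend_amplitude * frac
    rates = baselines[None, :] * trend * np.exp(spec.noise_sd * eps)
    rates = np.clip(rates, 0.0, None)

    frame = pd.DataFrame(
        rates,
        index=np.arange(spec.start_year, spec.end_year + 1),
        columns=[f"Country{i:03d}" for i in range(m)],
    )
    return MortalityPanel(frame=frame, value_kind="rate_percent")


def gen_exact_tail_curve(
    a: float, b: float, c: float, d: float, grid, n: int, k: int = 1
) -> AcerCurve:
    """Noise-free curve following exp{-(a*lambda+b)^c + d} exactly.

    ``n`` is the pseudo sample size: exceedance counts are the rounded
    expectations p * (n - k + 1).  Used as ground truth in fit-recovery
    tests.
    """
    grid = make_grid(grid)
    if a <= 0 or c <= 0:
        raise DomainError("tail parameters require a > 0 and c > 0")
    s = a * grid + b
    if np.any(s < 0):
        raise DomainError("a*lambda + b must be non-negative on the grid")
    p = np.exp(-np.power(s, c) + d)
    if np.any(p > 1):
        raise DomainError("parameters produce p > 1 on the grid")
    counts = np.round(p * (n - k + 1))
    return AcerCurve(lambdas=grid, p=p, exceed_counts=counts, k=k, n=n)
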
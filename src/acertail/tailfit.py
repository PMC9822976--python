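"""Sub-asymptotic tail fitting and return-level inversion.

Above a cut-on level lambda_0 the conditional exceedance rate is modelled by
the four-parameter Weibull-type form

    p_k(lambda) ~ exp{ -(a*lambda + b)^c + d },   lambda >= lambda_0,

with a > 0, c > 0 and a*lambda_0 + b >= 0.  The form is log-linearisable:
ln(d - ln p) = c * ln(a*lambda + b), so a nearly straight line in double-log
coordinates diagnoses a good tail fit.  Fitting minimises the weighted
squared error of ln p over the tail points; the weight of a point is the
inverse squared half-width of its confidence band on the ln scale, which
for the binomial-type band equals (N - k + 1) p / f^2 — i.e. points backed
by more observed exceedances count more, and widening a point's band can
only lower its influence.

The fitted form extrapolates the empirical curve (and, fitted separately,
each confidence-band boundary) to rare levels, and inverts in closed form
for the return level

    lambda* = ((d - ln p*)^(1/c) - b) / a

at a target probability p*, e.g. the level exceeded on average once per
100 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, DomainError, FitError
from .exceedance import AcerCurve, ConfidenceBand

log = logging.getLogger(__name__)

__all__ = [
    "TailParams",
    "FitDiagnostics",
    "ReturnSpec",
    "BandExtrapolation",
    "select_cuton",
    "fit_tail",
    "evaluate_tail",
    "extrapolate_band",
    "target_probability",
    "return_level",
]

#: multistart grid over the Weibull-type exponent c
C_STARTS = (0.5, 1.0, 2.0, 3.0)

#: levels whose empirical estimate rests on fewer exceedances than this are
#: excluded from the fit: with so few events the log-estimate is dominated by
#: discreteness and by the selection of levels that happen to be exceeded at
#: all, which biases the apparent tail upwards
MIN_TAIL_COUNT = 3


@dataclass(frozen=True)
class TailParams:
    """Fitted parameters (a, b, c, d) of the tail form above ``lambda0``."""

    a: float
    b: float
    c: float
    d: float
    lambda0: float
    k: int = 1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise DomainError("tail parameters require a > 0 and c > 0")
        if self.a * self.lambda0 + self.b < -1e-12:
            raise DomainError("a*lambda0 + b must be non-negative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class FitDiagnostics:
    """What the optimiser saw: objective, tail size, ln-ln linearity, starts."""

    objective: float
    n_points: int
    r_squared: float
    status: str
    start_costs: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ReturnSpec:
    """A return period together with the pooled event rate.

    ``events_per_year`` is the number of pooled local maxima per year of
    observation, N / T; for 195 annual country records it is ~195.
    """

    return_period_years: float
    events_per_year: float

    def __post_init__(self) -> None:
        if self.return_period_years <= 0 or self.events_per_year <= 0:
            raise DomainError("return period and event rate must be positive")


@dataclass(frozen=True)
class BandExtrapolation:
    """Tail-form extrapolation of the CI boundaries."""

    lambdas: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    params_lower: TailParams
    params_upper: TailParams


def evaluate_tail(params: TailParams, lambdas) -> np.ndarray:
    """Evaluate exp{-(a*lambda+b)^c + d} elementwise.

    Levels below ``lambda0`` are permitted (backward extrapolation) but a
    negative a*lambda + b is outside the model's domain.
    """
    lam = np.asarray(lambdas, dtype=float)
    s = params.a * lam + params.b
    if np.any(s < 0):
        raise DomainError("a*lambda + b < 0: level outside the tail model domain")
    out = np.exp(-np.power(s, params.c) + params.d)
    return out if lam.ndim else float(out)


def _tail_points(curve: AcerCurve, lambda0: float, min_count: float = MIN_TAIL_COUNT):
    mask = (
        (curve.lambdas >= lambda0)
        & (curve.p > 0)
        & (curve.exceed_counts >= min_count)
    )
    return curve.lambdas[mask], curve.p[mask]


def _weights(p: np.ndarray, n_effective: int) -> np.ndarray:
    # inverse squared ln-scale CI half-width (f/sqrt(n_eff p))^-2, up to the
    # constant f^2; equals the expected exceedance count
    return n_effective * p


def _residual_factory(lam, lnp, w, lambda0, fixed_c: float | None = None):
    sqw = np.sqrt(w / w.max())
    penalty = 1e3 * np.sqrt(len(lam))

    def residuals(theta):
        if fixed_c is None:
            a, b, c, d = np.exp(theta[0]), theta[1], np.exp(theta[2]), theta[3]
        else:
            a, b, c, d = np.exp(theta[0]), theta[1], fixed_c, theta[2]
        s = np.maximum(a * lam + b, 0.0)
        with np.errstate(over="ignore"):
            model = -np.minimum(np.power(s, c), 1e300) + d
        r = sqw * (lnp - model)
        s0 = a * lambda0 + b
        with np.errstate(over="ignore"):
            excess = d - min(max(s0, 0.0) ** c, 1e300)
        pen = np.array(
            [
                penalty * min(s0, 0.0),  # a*lambda0 + b >= 0
                penalty * max(excess, 0.0),  # p(lambda0) <= 1
            ]
        )
        return np.concatenate([r, pen])

    return residuals


def _initial_ab(lam, lnp, c0: float, d0: float, lambda0: float):
    """Linearised start: (d0 - ln p)^(1/c0) is ~ linear in lambda.

    Unweighted on purpose: fit weights concentrate on the bulk end of the
    tail, where local noise can flip the sign of a weighted slope; the
    start only needs the gross trend.  Falls back to the endpoint slope if
    the regression slope is non-positive.
    """
    y = np.power(np.maximum(d0 - lnp, 1e-12), 1.0 / c0)
    slope, intercept = np.polyfit(lam, y, 1)
    if slope <= 0:
        span = lam[-1] - lam[0]
        slope = (y[-1] - y[0]) / span if span > 0 else 1.0
        intercept = y[0] - slope * lam[0]
    a0 = max(float(slope), 1e-6)
    b0 = float(intercept)
    if a0 * lambda0 + b0 < 0:
        b0 = -a0 * lambda0
    return a0, b0


def _lnln_r_squared(lam, lnp, params: TailParams) -> float:
    """R^2 of the double-log linearity diagnostic ln(d - ln p) vs ln(a*lam + b)."""
    s = params.a * lam + params.b
    mask = (params.d - lnp > 0) & (s > 0)
    if mask.sum() < 3:
        return float("nan")
    y = np.log(params.d - lnp[mask])
    x = np.log(s[mask])
    if np.ptp(x) == 0:
        return float("nan")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_tail(
    curve: AcerCurve,
    band: ConfidenceBand | None = None,
    lambda0: float | None = None,
    min_points: int = 4,
    c_starts: Sequence[float] = C_STARTS,
    min_count: float = MIN_TAIL_COUNT,
    weight_mode: str = "counts",
    fix_c: float | None = None,
) -> tuple[TailParams, FitDiagnostics]:
    """Fit the four-parameter tail form to the curve above ``lambda0``.

    Weighted least squares on ln p with confidence-derived weights (see
    module docstring); a multistart over the exponent c guards against
    local minima, each start refined by a trust-region least-squares
    solver (an SQP-equivalent constrained optimiser).  Levels backed by
    fewer than ``min_count`` observed exceedances are excluded (their
    log-estimates carry a selection bias towards heavy tails).  With
    ``fix_c`` the exponent is held fixed and only (a, b, d) are fitted —
    used when a boundary curve must keep the shape of a central fit.
    """
    if lambda0 is None:
        raise DomainError("lambda0 (tail cut-on) is required")
    lam, p = _tail_points(curve, lambda0, min_count=min_count)
    if len(lam) < min_points:
        raise DataError(
            f"only {len(lam)} positive tail points at lambda >= {lambda0:g}; "
            f"need >= {min_points}"
        )
    if np.ptp(p) == 0:
        raise FitError("degenerate flat tail: all p equal, nothing to fit")
    lnp = np.log(p)
    if weight_mode == "counts":
        w = _weights(p, curve.n_effective)
    elif weight_mode == "uniform":
        w = np.ones_like(p)
    else:
        raise DomainError(f"unknown weight_mode {weight_mode!r}")
    residuals = _residual_factory(lam, lnp, w, lambda0, fixed_c=fix_c)

    best = None
    start_costs: dict[float, float] = {}
    d_cap = float(lnp.max())
    for c0 in c_starts if fix_c is None else (fix_c,):
        for d0 in (d_cap + 0.5, d_cap + 2.0):
            a0, b0 = _initial_ab(lam, lnp, c0, d0, lambda0)
            if fix_c is None:
                theta0 = np.array([np.log(a0), b0, np.log(c0), d0])
            else:
                theta0 = np.array([np.log(a0), b0, d0])
            try:
                sol = least_squares(
                    residuals,
                    theta0,
                    method="trf",
                    xtol=1e-13,
                    ftol=1e-13,
                    gtol=1e-13,
                    max_nfev=600,
                )
            except Exception as exc:  # pragma: no cover - solver hiccup
                log.debug("start c0=%g d0=%g failed: %s", c0, d0, exc)
                continue
            cost = float(sol.cost)
            start_costs[c0] = min(start_costs.get(c0, np.inf), cost)
            if best is None or cost < best[0]:
                best = (cost, sol)
    if best is None:
        raise FitError("tail fit failed on every start", diagnostics=start_costs)

    cost, sol = best
    if fix_c is None:
        a, b, c, d = (
            float(np.exp(sol.x[0])), float(sol.x[1]),
            float(np.exp(sol.x[2])), float(sol.x[3]),
        )
    else:
        a, b, c, d = float(np.exp(sol.x[0])), float(sol.x[1]), float(fix_c), float(sol.x[2])
    if a * lambda0 + b < 0:  # tolerate penalty slack at machine level
        b = -a * lambda0
    params = TailParams(a=a, b=b, c=c, d=d, lambda0=float(lambda0), k=curve.k)
    diag = FitDiagnostics(
        objective=cost,
        n_points=int(len(lam)),
        r_squared=_lnln_r_squared(lam, lnp, params),
        status=f"converged ({sol.status})" if sol.success else f"stopped ({sol.status})",
        start_costs=start_costs,
    )
    return params, diag


def select_cuton(
    curve: AcerCurve,
    strategy: str = "quantile",
    value: float | None = None,
    p_cuton: float = 0.5,
    stability_tol: float = 0.10,
    min_tail_points: int = 8,
) -> float:
    """Choose the tail cut-on lambda_0.

    ``manual``
        Return the configured ``value`` unchanged.
    ``quantile``
        Smallest grid level whose p has dropped to ``p_cuton`` (default
        0.5).  The sub-asymptotic form is flexible enough to track the
        curve from the median exceedance level outwards, and the wider
        fitting range substantially reduces the variance of the
        extrapolated return level compared with a cut-on deep in the tail.
    ``stability``
        Scan candidate cut-ons from the left and return the smallest whose
        fitted (a, b, c, d) agree with the next candidate's within
        ``stability_tol`` relative — the fit no longer depends on where the
        tail starts.
    """
    if len(curve.lambdas[curve.p > 0]) < min_tail_points:
        raise DataError(
            f"only {int((curve.p > 0).sum())} positive-p points; "
            f"need >= {min_tail_points}"
        )
    if strategy == "manual":
        if value is None:
            raise DomainError("manual cut-on strategy requires a value")
        return float(value)

    # for k > 1 the curve rises to a peak (at low levels the conditioning
    # event is rarely satisfied) before its decaying tail; only the
    # decaying branch is eligible as a cut-on
    peak = int(np.argmax(curve.p))
    decaying = (np.arange(len(curve.p)) >= peak) & (curve.p > 0)
    positive = curve.lambdas[decaying]
    if len(positive) < min_tail_points:
        raise DataError("too few positive points beyond the curve's peak")
    if strategy == "quantile":
        below = curve.lambdas[decaying & (curve.p <= p_cuton)]
        # keep enough tail points to the right of the cut-on
        cap = positive[-min_tail_points]
        if len(below) == 0:
            return float(min(positive[0], cap))
        return float(min(below[0], cap))
    if strategy == "stability":
        eligible = positive[positive <= positive[-min_tail_points]]
        n_cand = min(10, len(eligible))
        candidates = eligible[np.linspace(0, len(eligible) - 1, n_cand).astype(int)]
        fits = []
        for lam0 in candidates:
            try:
                params, _ = fit_tail(curve, lambda0=float(lam0))
                fits.append((float(lam0), np.array(params.as_tuple())))
            except (DataError, FitError):
                continue
        changes = []
        for (lam0, th0), (_, th1) in zip(fits, fits[1:]):
            denom = np.maximum(np.abs(th0), 0.1)
            changes.append((lam0, float(np.max(np.abs(th1 - th0) / denom))))
        for lam0, change in changes:
            if change <= stability_tol:
                return lam0
        if changes:
            log.warning("no stable cut-on found; using the least-varying candidate")
            return min(changes, key=lambda t: t[1])[0]
        raise DataError("stability scan could not fit any candidate cut-on")
    raise DomainError(f"unknown cut-on strategy {strategy!r}")


def extrapolate_band(
    band: ConfidenceBand,
    curve: AcerCurve,
    lambda0: float,
    lambdas,
    central: TailParams | None = None,
    source: str = "fitted",
) -> BandExtrapolation:
    """Fit the tail form separately to the CI- and CI+ boundary curves.

    With ``source="fitted"`` (default, requires ``central``) the boundary
    points carry the band's multiplier structure evaluated around the
    fitted central curve, p_fit (1 +- f / sqrt((N-k+1) p_fit)): the
    boundaries are then smooth, always bracket the central fit over the
    data range, and their Eq.-10 extrapolations are stable.  With
    ``source="empirical"`` the raw empirical boundary points are fitted
    directly; they inherit the sampling noise of the far tail, which makes
    the extrapolated interval itself noisy.  Either way each boundary is
    fitted with uniform weights over the tail points — count-weighting
    would mute the sparse far tail, where the boundary's departure from
    the central curve lives, and collapse the band onto the central fit.
    If a central fit is supplied the bracketing CI- <= p <= CI+ is checked
    post hoc and a violation is logged, not raised.
    """
    lam_eval = np.asarray(lambdas, dtype=float)
    if source not in ("fitted", "empirical"):
        raise DomainError(f"unknown band source {source!r}")
    if source == "fitted" and central is None:
        raise DomainError("source='fitted' requires the central tail parameters")

    if source == "fitted":
        grid_mask = curve.lambdas >= lambda0
        lam_fit = curve.lambdas[grid_mask]
        p_fit = evaluate_tail(central, lam_fit)
        with np.errstate(divide="ignore"):
            half = band.multiplier / np.sqrt(curve.n_effective * p_fit)
        boundaries = (
            ("lower", lam_fit, p_fit * (1 - half), p_fit * curve.n_effective),
            ("upper", lam_fit, p_fit * (1 + half), p_fit * curve.n_effective),
        )
    else:
        boundaries = []
        for name, boundary in (("lower", band.lower), ("upper", band.upper)):
            mask = (curve.lambdas >= lambda0) & np.isfinite(boundary) & (boundary > 0)
            boundaries.append(
                (name, curve.lambdas[mask], boundary[mask], curve.exceed_counts[mask])
            )

    out = {}
    for name, lam_b, p_b, counts_b in boundaries:
        keep = p_b > 0
        lam_b, p_b, counts_b = lam_b[keep], p_b[keep], counts_b[keep]
        if len(lam_b) < 4:
            raise DataError(
                f"confidence band {name} boundary has {len(lam_b)} usable "
                f"tail points; need >= 4"
            )
        proxy = AcerCurve(
            lambdas=lam_b,
            p=np.clip(p_b, None, 1.0),
            exceed_counts=counts_b,
            k=curve.k,
            n=curve.n,
        )
        params, _ = fit_tail(proxy, lambda0=lambda0, weight_mode="uniform")
        out[name] = (params, evaluate_tail(params, lam_eval))

    (p_lo, lo), (p_hi, hi) = out["lower"], out["upper"]
    if central is not None:
        # near the cut-on the band is thin and the boundary family's small
        # approximation error can cross the central curve; clip the
        # evaluated boundaries to bracket, and warn only when the crossing
        # is material (the far-tail region driving inversions is ordered)
        centre = evaluate_tail(central, lam_eval)
        if np.any(lo > centre * 1.25) or np.any(hi < centre * 0.8):
            log.warning("extrapolated CI boundaries do not bracket the central curve")
        lo = np.minimum(lo, centre)
        hi = np.maximum(hi, centre)
    return BandExtrapolation(
        lambdas=lam_eval, lower=lo, upper=hi, params_lower=p_lo, params_upper=p_hi
    )


def target_probability(spec: ReturnSpec, convention: str = "expected_exceedance") -> float:
    """Convert a return period to a target conditional exceedance rate.

    ``expected_exceedance`` (default): p* = 1 / (events_per_year * T) — the
    rate at which the expected number of exceedances over the return period
    equals one.  ``annual_nonexceedance``: p* = -ln(1 - 1/T) /
    events_per_year — the rate at which the probability of a year with no
    exceedance is 1 - 1/T.  The two agree to first order for large T.
    """
    nu, t = spec.events_per_year, spec.return_period_years
    if convention == "expected_exceedance":
        return 1.0 / (nu * t)
    if convention == "annual_nonexceedance":
        if t <= 1:
            raise DomainError("annual_nonexceedance requires a return period > 1 year")
        return float(-np.log1p(-1.0 / t) / nu)
    raise DomainError(f"unknown return-period convention {convention!r}")


def return_level(params: TailParams, p_target: float) -> float:
    """Invert the tail form: the level lambda* with p(lambda*) = p_target."""
    if p_target <= 0:
        raise DomainError("target probability must be positive")
    p_at_cuton = evaluate_tail(params, params.lambda0)
    if p_target >= p_at_cuton:
        raise DomainError(
            f"target probability {p_target:g} is not below the tail range "
            f"(p(lambda0) = {p_at_cuton:g})"
        )
    lam_star = ((params.d - np.log(p_target)) ** (1.0 / params.c) - params.b) / params.a
    return float(lam_star)
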
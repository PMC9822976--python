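"""Model / Results interface tying the pipeline together.

:class:`AcerModel` wraps a pooled merged vector (built directly, or from a
panel via :meth:`AcerModel.from_panel` / :meth:`AcerModel.from_dataframe`)
and a lambda grid.  :meth:`AcerModel.fit` runs the full chain —
conditional-exceedance estimation with convergence in k, confidence band,
cut-on selection, tail fit, band extrapolation and return-level inversion —
and returns an :class:`AcerResults` carrying estimates, uncertainties and
diagnostics, with ``summary()``, plotting and the half-data validation
scheme hanging off it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .exceedance import (
    AcerCurve,
    ConfidenceBand,
    ConvergenceResult,
    confidence_band,
    convergence_in_k,
    default_grid,
    empirical_pk,
    make_grid,
)
from .merge import MergedVector, merge_panel
from .panel import FailureLimits, MortalityPanel, ScaledPanel, scale_components
from .tailfit import (
    BandExtrapolation,
    FitDiagnostics,
    ReturnSpec,
    TailParams,
    evaluate_tail,
    extrapolate_band,
    fit_tail,
    return_level,
    select_cuton,
    target_probability,
)

log = logging.getLogger(__name__)

__all__ = ["AcerModel", "AcerResults", "HalfDataValidation"]


class AcerModel:
    """Conditional-exceedance tail model for a pooled multi-component record.

    Parameters
    ----------
    merged
        The pooled, time-ordered vector of local maxima with its unified
        limit vector.
    grid
        Lambda levels at which the exceedance rates are estimated; defaults
        to 200 equally spaced levels from the 5th percentile of R/eta to
        its maximum.
    """

    def __init__(self, merged: MergedVector, grid: Sequence[float] | None = None):
        self.merged = merged
        self.grid = default_grid(merged) if grid is None else make_grid(grid)
        log.info(
            "AcerModel: N=%d pooled maxima from %d components over %g years "
            "(%.1f events/year)",
            merged.n, merged.n_components, merged.span_t, merged.events_per_year,
        )

    @classmethod
    def from_panel(
        cls,
        panel: MortalityPanel | ScaledPanel,
        limits: FailureLimits | Mapping[str, float] | float | None = None,
        mode: str = "all_samples",
        grid: Sequence[float] | None = None,
    ) -> "AcerModel":
        """Build the model from a panel, scaling by failure limits first.

        A :class:`MortalityPanel` is scaled by ``limits`` (uniform 100 for
        rate_percent panels converts to population fractions if limits are
        omitted); a :class:`ScaledPanel` is pooled as-is with unified
        limit 1.
        """
        if isinstance(panel, MortalityPanel):
            if limits is None:
                if panel.value_kind == "rate_percent":
                    limits = FailureLimits.uniform(panel.entities, 100.0)
                else:
                    raise DomainError(
                        "failure limits are required for a counts panel"
                    )
            elif not isinstance(limits, FailureLimits):
                if isinstance(limits, Mapping):
                    limits = FailureLimits.from_mapping(limits)
                else:
                    limits = FailureLimits.uniform(panel.entities, float(limits))
            scaled = scale_components(panel, limits)
        else:
            scaled = panel
        merged = merge_panel(scaled, mode=mode)
        return cls(merged, grid=grid)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        value_kind: str = "rate_percent",
        **kwargs,
    ) -> "AcerModel":
        """Build from a wide year x entity DataFrame."""
        panel = MortalityPanel(frame=frame, value_kind=value_kind)
        return cls.from_panel(panel, **kwargs)

    def empirical(self, k: int) -> AcerCurve:
        """The empirical p_k curve on the model grid."""
        return empirical_pk(self.merged, k, self.grid)

    def fit(
        self,
        k: int | None = None,
        k_max: int = 4,
        conf: float = 0.95,
        lambda0: float | None = None,
        cuton_strategy: str = "quantile",
        return_period: float = 100.0,
        convention: str = "expected_exceedance",
        extrapolate_to: float | None = None,
    ) -> "AcerResults":
        """Run the full estimation chain and return the results object.

        If ``k`` is None the conditioning level is selected by convergence
        in k (smallest settled k up to ``k_max``).  If ``lambda0`` is None
        the cut-on comes from ``cuton_strategy``; passing a value forces
        the manual strategy.
        """
        convergence: ConvergenceResult | None = None
        if k is None:
            convergence = convergence_in_k(self.merged, self.grid, k_max=k_max)
            k = convergence.k_star
            curve = convergence.curves[k]
        else:
            curve = self.empirical(k)

        band = confidence_band(curve, conf)
        if lambda0 is None:
            lambda0 = select_cuton(curve, strategy=cuton_strategy)
        else:
            lambda0 = select_cuton(curve, strategy="manual", value=lambda0)

        params, diagnostics = fit_tail(curve, band=band, lambda0=lambda0)

        spec = ReturnSpec(
            return_period_years=return_period,
            events_per_year=self.merged.events_per_year,
        )
        p_target = target_probability(spec, convention=convention)
        lam_star = return_level(params, p_target)

        hi = max(float(self.grid[-1]), lam_star * 1.05)
        if extrapolate_to is not None:
            hi = max(hi, extrapolate_to)
        lam_extra = np.linspace(lambda0, hi, 200)
        band_extra = extrapolate_band(
            band, curve, lambda0, lam_extra, central=params
        )
        # return-level uncertainty: invert the extrapolated CI boundaries at
        # the same target probability — the lower boundary (a thinner
        # plausible tail) crosses p_target at a smaller level
        ci = {}
        for name, bp in (
            ("lower", band_extra.params_lower),
            ("upper", band_extra.params_upper),
        ):
            try:
                ci[name] = return_level(bp, p_target)
            except DomainError:
                ci[name] = float("nan")
        # the interval always contains the point estimate
        lam_ci = (
            min(ci["lower"], lam_star) if np.isfinite(ci["lower"]) else ci["lower"],
            max(ci["upper"], lam_star) if np.isfinite(ci["upper"]) else ci["upper"],
        )

        return AcerResults(
            model=self,
            curve=curve,
            band=band,
            convergence=convergence,
            params=params,
            diagnostics=diagnostics,
            band_extrapolation=band_extra,
            return_spec=spec,
            convention=convention,
            p_target=p_target,
            return_level_=lam_star,
            return_level_ci_=lam_ci,
            conf=conf,
        )


@dataclass(frozen=True)
class HalfDataValidation:
    """Outcome of the every-second-point validation scheme."""

    lambda_full: float
    lambda_half: float
    ci: tuple[float, float]
    inside: bool


@dataclass(frozen=True)
class AcerResults:
    """Estimates, uncertainty and diagnostics of a fitted tail model."""

    model: AcerModel
    curve: AcerCurve
    band: ConfidenceBand
    convergence: ConvergenceResult | None
    params: TailParams
    diagnostics: FitDiagnostics
    band_extrapolation: BandExtrapolation
    return_spec: ReturnSpec
    convention: str
    p_target: float
    return_level_: float
    return_level_ci_: tuple[float, float]
    conf: float

    @property
    def k(self) -> int:
        return self.curve.k

    @property
    def lambda0(self) -> float:
        return self.params.lambda0

    def predict(self, lambdas) -> np.ndarray:
        """Tail-model p(lambda) at the requested levels."""
        return evaluate_tail(self.params, lambdas)

    def return_level_for(self, return_period: float, convention: str | None = None) -> float:
        """Return level for an alternative return period (same fit)."""
        spec = ReturnSpec(
            return_period_years=return_period,
            events_per_year=self.return_spec.events_per_year,
        )
        p = target_probability(spec, convention=convention or self.convention)
        return return_level(self.params, p)

    def validate_half_data(self) -> HalfDataValidation:
        """The validation scheme: refit on every second pooled point.

        The subsampled record is fitted with the same conditioning level
        and cut-on, its prediction taken at the full-data target
        probability, and compared against the full-data extrapolated
        confidence interval of the return level.
        """
        half = self.model.merged.subsample(2)
        half_model = AcerModel(half, grid=self.model.grid)
        curve = half_model.empirical(self.k)
        params, _ = fit_tail(
            curve, band=confidence_band(curve, self.conf), lambda0=self.lambda0
        )
        lam_half = return_level(params, self.p_target)
        lo, hi = self.return_level_ci_
        inside = bool(lo <= lam_half <= hi)
        return HalfDataValidation(
            lambda_full=self.return_level_,
            lambda_half=lam_half,
            ci=self.return_level_ci_,
            inside=inside,
        )

    def summary(self, percent: bool = True) -> str:
        """Plain-text summary table of the fit."""
        scale = 100.0 if percent else 1.0
        unit = "% of failure limit" if percent else "fraction of failure limit"
        m = self.model.merged
        conv = self.convergence
        lo, hi = self.return_level_ci_
        lines = [
            "ACER tail model results",
            "=" * 58,
            f"{'Pooled maxima N':<34}{m.n:>24d}",
            f"{'Components':<34}{m.n_components:>24d}",
            f"{'Observation span T (years)':<34}{m.span_t:>24.1f}",
            f"{'Events per year':<34}{m.events_per_year:>24.2f}",
            f"{'Conditioning level k':<34}{self.k:>24d}",
        ]
        if conv is not None:
            lines.append(
                f"{'Convergence in k':<34}"
                f"{('settled' if conv.converged else 'NOT settled'):>24}"
            )
        lines += [
            f"{'Tail cut-on lambda0':<34}{self.lambda0 * scale:>23.4f}{'%' if percent else ''}",
            f"{'Tail points used':<34}{self.diagnostics.n_points:>24d}",
            f"{'ln-ln linearity R^2':<34}{self.diagnostics.r_squared:>24.5f}",
            "-" * 58,
            f"{'a':<10}{self.params.a:>16.6g}    {'b':<6}{self.params.b:>16.6g}",
            f"{'c':<10}{self.params.c:>16.6g}    {'d':<6}{self.params.d:>16.6g}",
            "-" * 58,
            f"{'Return period (years)':<34}{self.return_spec.return_period_years:>24.0f}",
            f"{'Convention':<34}{self.convention:>24}",
            f"{'Target probability p*':<34}{self.p_target:>24.3e}",
            f"{'Return level lambda*':<34}{self.return_level_ * scale:>23.4f}{'%' if percent else ''}",
            f"{f'{self.conf:.0%} CI for lambda*':<34}"
            f"{f'[{lo * scale:.4f}, {hi * scale:.4f}]':>24}",
            "=" * 58,
            f"Levels expressed in {unit}.",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable fit report."""
        lo, hi = self.return_level_ci_
        return {
            "n": self.model.merged.n,
            "n_components": self.model.merged.n_components,
            "span_years": self.model.merged.span_t,
            "events_per_year": self.model.merged.events_per_year,
            "k": self.k,
            "converged_in_k": None if self.convergence is None else self.convergence.converged,
            "lambda0": self.lambda0,
            "params": dict(zip("abcd", self.params.as_tuple())),
            "r_squared_lnln": self.diagnostics.r_squared,
            "objective": self.diagnostics.objective,
            "return_period_years": self.return_spec.return_period_years,
            "convention": self.convention,
            "p_target": self.p_target,
            "return_level": self.return_level_,
            "return_level_ci": [lo, hi],
            "confidence_level": self.conf,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot(self, ax=None, percent: bool = True):
        """Fig-4-style plot: log-scale p versus lambda with CI and the star."""
        from .plotting import plot_tail_fit

        return plot_tail_fit(self, ax=ax, percent=percent)
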
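"""Pooling per-component local maxima into one time-ordered vector R.

Each component series X(t), Y(t), ... contributes its local maxima at
strictly increasing time instants.  All maxima are blended, in
non-decreasing time order, into a single synthetic vector
R = (R_1, ..., R_N) with N = N_X + N_Y + ..., together with the unified
limit vector (eta_1, ..., eta_N) carrying, for each element, the failure
limit of the component that produced it.  No observation is lost: the
multiset of (value, component) pairs is preserved exactly.

For coarse annual panels the default is to treat every sample as a local
maximum (``all_samples``); ``strict_peaks`` extracts interior points
strictly above both neighbours, appropriate for densely sampled processes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .panel import FailureLimits, MortalityPanel, ScaledPanel

__all__ = [
    "ComponentMaxima",
    "MergedVector",
    "extract_local_maxima",
    "merge_maxima",
    "merge_panel",
]


@dataclass(frozen=True)
class ComponentMaxima:
    """Local maxima of one component at strictly increasing time instants."""

    component_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise DomainError("times and values must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DomainError(
                f"times of component {self.component_id!r} must be strictly increasing"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MergedVector:
    """The pooled vector R with its unified limit vector.

    Attributes
    ----------
    values, times, source, limits
        Element j holds the j-th pooled local maximum R_j, its time, the
        id of the component that produced it and that component's failure
        limit eta_j.  Times are non-decreasing; exact ties keep the input
        component order.
    span_t
        Total observation time T.  For annual integer times this is
        last year - first year + 1.
    """

    values: np.ndarray
    times: np.ndarray
    source: np.ndarray
    limits: np.ndarray
    span_t: float
    n_components: int

    def __post_init__(self) -> None:
        for name in ("values", "times", "limits"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "source", np.asarray(self.source, dtype=object))
        n = len(self.values)
        if n == 0:
            raise DataError("merged vector is empty")
        if not (len(self.times) == len(self.source) == len(self.limits) == n):
            raise DomainError("merged vector fields must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise DomainError("merged times must be non-decreasing")
        if np.any(self.limits <= 0):
            raise DomainError("unified limits must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def scaled(self) -> np.ndarray:
        """R_j / eta_j — exceedance of level lambda means scaled > lambda."""
        return self.values / self.limits

    @property
    def events_per_year(self) -> float:
        return self.n / self.span_t

    def subsample(self, step: int = 2, offset: int = 0) -> "MergedVector":
        """Every ``step``-th element (validation scheme); the span is unchanged."""
        if self.n < step:
            raise DataError(f"cannot subsample a vector of length {self.n} by {step}")
        idx = np.arange(offset, self.n, step)
        return MergedVector(
            values=self.values[idx],
            times=self.times[idx],
            source=self.source[idx],
            limits=self.limits[idx],
            span_t=self.span_t,
            n_components=self.n_components,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "value": self.values,
                "component": self.source,
                "eta": self.limits,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, span_t: float | None = None
    ) -> "MergedVector":
        components = pd.unique(frame["component"])
        if span_t is None:
            span_t = _default_span(frame["time"].to_numpy())
        return cls(
            values=frame["value"].to_numpy(dtype=float),
            times=frame["time"].to_numpy(dtype=float),
            source=frame["component"].to_numpy(dtype=object),
            limits=frame["eta"].to_numpy(dtype=float),
            span_t=float(span_t),
            n_components=len(components),
        )

    @classmethod
    def from_csv(cls, path, span_t: float | None = None) -> "MergedVector":
        return cls.from_frame(pd.read_csv(path), span_t=span_t)


def _default_span(times: np.ndarray) -> float:
    """Annual integer instants span last - first + 1 years; otherwise last - first."""
    t = np.asarray(times, dtype=float)
    lo, hi = t.min(), t.max()
    if np.allclose(t, np.round(t)):
        return float(hi - lo + 1)
    return float(hi - lo) if hi > lo else 1.0


def extract_local_maxima(
    values: Sequence[float],
    times: Sequence[float] | None = None,
    mode: str = "all_samples",
    component_id: str = "",
) -> ComponentMaxima:
    """Extract the local-maxima record of one component series.

    ``strict_peaks`` keeps interior points strictly greater than both
    neighbours; ``all_samples`` keeps every sample, the appropriate reading
    of a coarse annual record where each observation is the year's level.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise DomainError("series must be a non-empty 1-D sequence")
    t = np.arange(len(v), dtype=float) if times is None else np.asarray(times, dtype=float)
    if len(t) != len(v):
        raise DomainError("times and values differ in length")
    if mode == "all_samples":
        return ComponentMaxima(component_id=component_id, times=t, values=v)
    if mode == "strict_peaks":
        if len(v) < 3:
            raise DomainError("strict_peaks requires a series of length >= 3")
        interior = np.arange(1, len(v) - 1)
        mask = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
        idx = interior[mask]
        return ComponentMaxima(component_id=component_id, times=t[idx], values=v[idx])
    raise DomainError(f"unknown extraction mode {mode!r}")


def merge_maxima(
    components: Sequence[ComponentMaxima],
    limits: FailureLimits | Mapping[str, float] | float = 1.0,
    span_t: float | None = None,
) -> MergedVector:
    """Merge component maxima into the single time-ordered vector R.

    Elements are sorted by time with a stable tie-break (input component
    order), so permuting the input only reorders exact time ties.  Each
    element carries the eta of its source component.
    """
    nonempty = [c for c in components if len(c) > 0]
    if not nonempty:
        raise DataError("no local maxima to merge")

    if isinstance(limits, FailureLimits):
        eta_of = {c.component_id: limits[c.component_id] for c in nonempty}
    elif isinstance(limits, Mapping):
        eta_of = {c.component_id: float(limits[c.component_id]) for c in nonempty}
    else:
        eta_of = {c.component_id: float(limits) for c in nonempty}

    times = np.concatenate([c.times for c in nonempty])
    values = np.concatenate([c.values for c in nonempty])
    source = np.concatenate(
        [np.full(len(c), c.component_id, dtype=object) for c in nonempty]
    )
    etas = np.concatenate([np.full(len(c), eta_of[c.component_id]) for c in nonempty])

    order = np.argsort(times, kind="stable")
    if span_t is None:
        span_t = _default_span(times)
    return MergedVector(
        values=values[order],
        times=times[order],
        source=source[order],
        limits=etas[order],
        span_t=float(span_t),
        n_components=len(nonempty),
    )


def merge_panel(
    panel: ScaledPanel | MortalityPanel,
    mode: str = "all_samples",
    limits: FailureLimits | Mapping[str, float] | float = 1.0,
) -> MergedVector:
    """Convenience: extract maxima of every panel column and merge them.

    For a :class:`ScaledPanel` the unified limit is 1 by construction.
    """
    years = panel.years.astype(float)
    comps = [
        extract_local_maxima(
            panel.frame[c].to_numpy(dtype=float), years, mode=mode, component_id=str(c)
        )
        for c in panel.frame.columns
    ]
    return merge_maxima(comps, limits=limits)
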
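"""Reading, validating and scaling multi-entity annual mortality panels.

A panel is a rectangular year x entity table of non-negative values (death
counts or death rates).  Each entity (country, region, ...) has a positive
*failure limit* eta — here typically its population, so that the scaled
series value/eta is the death rate as a fraction of the local population and
every component shares the unified failure limit 1.

Two CSV dialects are supported:

* the long "causes of death" layout used by ourworldindata.org
  (``Entity, Code, Year, <cause columns...>``), auto-detected from its
  header names;
* a generic wide panel (one year column or index, one column per entity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "MortalityPanel",
    "FailureLimits",
    "ScaledPanel",
    "read_owid_panel",
    "read_wide_panel",
    "read_panel",
    "exclude_entities",
    "scale_components",
]

#: recognised kinds of raw panel values
VALUE_KINDS = ("counts", "rate_percent", "non_dimensional")


@dataclass(frozen=True)
class MortalityPanel:
    """Rectangular set of per-entity annual non-negative values.

    Parameters
    ----------
    frame
        DataFrame indexed by strictly increasing integer years, one column
        per entity.  No missing cells are allowed: entities with gaps must
        be dropped before construction.
    value_kind
        ``"counts"`` for raw death counts, ``"rate_percent"`` for deaths as
        a percentage of local population, ``"non_dimensional"`` after
        scaling by failure limits.
    """

    frame: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ConfigurationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.frame.shape[1] == 0:
            raise DataError("panel has no entities")
        years = np.asarray(self.frame.index)
        if len(years) == 0:
            raise DataError("panel has no years")
        if not np.issubdtype(years.dtype, np.integer):
            raise ConfigurationError("panel index must be integer calendar years")
        if len(years) > 1 and not np.all(np.diff(years) > 0):
            raise ConfigurationError("panel years must be strictly increasing")
        if self.frame.isna().any().any():
            raise DataError("panel contains missing cells; drop gapped entities first")
        if self.value_kind != "non_dimensional" and (self.frame.to_numpy() < 0).any():
            raise DataError("panel values must be non-negative")

    @property
    def entities(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_entities(self) -> int:
        return self.frame.shape[1]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="year")


@dataclass(frozen=True)
class FailureLimits:
    """Per-entity positive critical thresholds eta.

    For mortality panels the natural choice is the entity's population, so
    that value/eta is a death rate as a population fraction; for panels
    already expressed in per cent of population, ``uniform(entities, 100)``
    converts per-cent values to the same fraction scale.
    """

    limits: pd.Series

    def __post_init__(self) -> None:
        if (self.limits <= 0).any():
            bad = self.limits.index[self.limits <= 0].tolist()
            raise DomainError(f"failure limits must be positive; offending: {bad}")

    @classmethod
    def uniform(cls, entities: Iterable[str], value: float = 1.0) -> "FailureLimits":
        entities = list(entities)
        return cls(pd.Series(float(value), index=entities))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "FailureLimits":
        return cls(pd.Series(mapping, dtype=float))

    def __getitem__(self, entity: str) -> float:
        return float(self.limits[entity])

    def for_entities(self, entities: Sequence[str]) -> np.ndarray:
        missing = [e for e in entities if e not in self.limits.index]
        if missing:
            raise ConfigurationError(f"no failure limit for entities: {missing}")
        return self.limits.loc[list(entities)].to_numpy(dtype=float)


@dataclass(frozen=True)
class ScaledPanel:
    """A panel made non-dimensional: every value divided by its entity's eta.

    After scaling all components share the unified failure limit 1, so a
    single scaling parameter lambda lowers every limit at once.  Values may
    be negative for synthetic Gaussian test panels; mortality panels are
    non-negative by construction.
    """

    frame: pd.DataFrame
    limits: FailureLimits = field(
        default_factory=lambda: FailureLimits(pd.Series(dtype=float))
    )

    @property
    def entities(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="year")

    @classmethod
    def from_csv(cls, path) -> "ScaledPanel":
        frame = pd.read_csv(path, index_col="year")
        frame.index = frame.index.astype(int)
        return cls(frame=frame)


def _find_column(columns: Sequence[str], name: str) -> str | None:
    lowered = {c.lower(): c for c in columns}
    return lowered.get(name.lower())


def is_owid_dialect(columns: Sequence[str]) -> bool:
    """The long OWID layout is recognised by its Entity and Year headers."""
    return _find_column(columns, "entity") is not None and _find_column(
        columns, "year"
    ) is not None


def read_owid_panel(
    path,
    cause_column: str,
    population_column: str | None = None,
    span: tuple[int, int] | None = None,
) -> MortalityPanel:
    """Read a long-format OWID-style causes-of-death CSV into a panel.

    Parameters
    ----------
    path
        CSV with at least Entity, Year and the named cause column (a Code
        column is tolerated and ignored).
    cause_column
        Column holding the death counts (or rates) to analyse.
    population_column
        If given, values are converted to rate_percent =
        100 * deaths / population.
    span
        Inclusive (start_year, end_year); entities whose coverage of the
        span is incomplete are excluded with a log message.  Defaults to
        the widest span present.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    raw = pd.read_csv(path)
    entity_col = _find_column(raw.columns, "entity")
    year_col = _find_column(raw.columns, "year")
    if entity_col is None or year_col is None:
        raise ConfigurationError(
            "not an OWID-style file: Entity/Year header columns missing"
        )
    for col in filter(None, (cause_column, population_column)):
        if col not in raw.columns:
            raise ConfigurationError(f"column {col!r} not found in {path.name}")

    numeric_cols = [cause_column] + ([population_column] if population_column else [])
    for col in numeric_cols + [year_col]:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value in column {col!r} at CSV row {bad[0] + 2}"
            )
        raw[col] = coerced

    raw = raw.dropna(subset=[cause_column])
    if population_column is not None:
        raw = raw.dropna(subset=[population_column])
        raw = raw[raw[population_column] > 0]
        values = 100.0 * raw[cause_column] / raw[population_column]
        kind = "rate_percent"
    else:
        values = raw[cause_column]
        kind = "counts"

    table = pd.DataFrame(
        {
            "entity": raw[entity_col].astype(str),
            "year": raw[year_col].astype(int),
            "value": values.to_numpy(dtype=float),
        }
    )
    wide = table.pivot_table(index="year", columns="entity", values="value")
    if span is None:
        span = (int(wide.index.min()), int(wide.index.max()))
    wide = wide.loc[(wide.index >= span[0]) & (wide.index <= span[1])]
    expected_years = np.arange(span[0], span[1] + 1)
    wide = wide.reindex(expected_years)

    complete = wide.columns[wide.notna().all(axis=0)]
    dropped = [c for c in wide.columns if c not in set(complete)]
    if dropped:
        log.warning(
            "excluding %d entities with incomplete %d-%d coverage: %s",
            len(dropped), span[0], span[1],
            ", ".join(map(str, dropped[:10])) + ("..." if len(dropped) > 10 else ""),
        )
    wide = wide[complete]
    if wide.shape[1] == 0:
        raise DataError(f"no entity fully covers the span {span[0]}-{span[1]}")
    wide.index = wide.index.astype(int)
    wide.columns.name = None
    wide.index.name = None
    return MortalityPanel(frame=wide, value_kind=kind)


def read_wide_panel(path, value_kind: str = "counts") -> MortalityPanel:
    """Read a generic wide panel: a year column/index plus one column per entity."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    frame = pd.read_csv(path)
    year_col = _find_column(frame.columns, "year")
    if year_col is not None:
        frame = frame.set_index(year_col)
    else:
        frame = frame.set_index(frame.columns[0])
    try:
        frame.index = frame.index.astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"first column of {path.name} is not integer years") from exc
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if frame.isna().any().any():
        row = int(frame.index[frame.isna().any(axis=1)][0])
        raise ParseError(f"non-numeric or missing cell at year {row} in {path.name}")
    frame.index.name = None
    return MortalityPanel(frame=frame, value_kind=value_kind)


def read_panel(
    path,
    cause_column: str | None = None,
    value_kind: str = "rate_percent",
    **kwargs,
) -> MortalityPanel:
    """Dispatch on dialect: OWID long format if Entity/Year headers are present.

    ``value_kind`` applies to the wide dialect only (the OWID reader infers
    it from whether a population column is given).
    """
    header = pd.read_csv(path, nrows=0).columns
    if is_owid_dialect(header):
        if cause_column is None:
            raise ConfigurationError("cause_column is required for OWID-style input")
        return read_owid_panel(path, cause_column, **kwargs)
    kwargs.pop("population_column", None)
    kwargs.pop("span", None)
    return read_wide_panel(path, value_kind=value_kind, **kwargs)


def exclude_entities(panel: MortalityPanel, names: Sequence[str]) -> MortalityPanel:
    """Drop the named entity columns, preserving the order of the rest.

    Names absent from the panel are ignored with a warning; removing every
    entity is an error.
    """
    present = set(panel.entities)
    missing = [n for n in names if n not in present]
    if missing:
        log.warning("exclusion list names absent entities (ignored): %s", missing)
    keep = [c for c in panel.entities if c not in set(names)]
    if not keep:
        raise DataError("exclusion list removes every entity")
    if len(keep) == len(panel.entities):
        return panel
    return MortalityPanel(frame=panel.frame[keep], value_kind=panel.value_kind)


def scale_components(panel: MortalityPanel, limits: FailureLimits) -> ScaledPanel:
    """Divide each component by its failure limit eta (X -> X/eta_X).

    The result is non-dimensional with unified failure limit 1; a scaled
    value of 0.0024 is a death rate of 0.24 % of the local population.
    """
    eta = limits.for_entities(panel.entities)
    scaled = panel.frame / eta
    return ScaledPanel(frame=scaled, limits=limits)
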
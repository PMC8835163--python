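"""Orientation harmonisation of indicator variables.

Composite indices require every component variable to point the same way:
"more is better".  Raw indicators come in three orientations —

* **stimulant**: higher is better (GDP, real-wage index);
* **destimulant**: lower is better (unemployment rate, budget deficit);
* **nominant**: closest to a target is better (an inflation index with a
  central-bank target).

Destimulants are mapped to ``x' = min_t(x) / x`` and nominants to
``x' = x/c`` below the target ``c`` and ``c/x`` above it, so every
converted series lies in ``(0, 1]`` and equals 1 at its best observed
(or target) value.  Stimulants pass through unchanged — every downstream
index is a ratio to a benchmark, so no further normalisation is needed.

The minimum in the destimulant formula is taken over the full loaded
analysis window.  Non-positive values are rejected rather than clamped:
both formulas are undefined there, and silent clamping would distort the
benchmarks computed later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConversionError

__all__ = [
    "Orientation",
    "IndicatorSeries",
    "IndicatorPanel",
    "convert_destimulant",
    "convert_nominant",
    "convert_panel",
]


class Orientation(str, Enum):
    STIMULANT = "stimulant"
    DESTIMULANT = "destimulant"
    NOMINANT = "nominant"


@dataclass(frozen=True)
class IndicatorSeries:
    """One indicator variable observed over consecutive periods.

    Parameters
    ----------
    name
        Variable label.
    values
        Ordered observations, one per period.
    orientation
        Direction of preference; see module docstring.
    target
        Nominant target value ``c > 0``; required iff ``orientation`` is
        nominant.
    """

    name: str
    values: np.ndarray
    orientation: Orientation = Orientation.STIMULANT
    target: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ConversionError(f"series {self.name!r}: values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise ConversionError(f"series {self.name!r}: values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if self.orientation is Orientation.NOMINANT:
            if self.target is None:
                raise ConversionError(f"series {self.name!r}: nominant orientation requires a target")
            if not (self.target > 0 and np.isfinite(self.target)):
                raise ConversionError(f"series {self.name!r}: nominant target must be a finite positive number")
        elif self.target is not None:
            raise ConversionError(f"series {self.name!r}: target is only meaningful for nominant orientation")

    def __len__(self) -> int:
        return self.values.size


def _require_positive(series: IndicatorSeries) -> None:
    if np.any(series.values <= 0):
        raise ConversionError(
            f"series {series.name!r}: conversion requires strictly positive values "
            f"(min = {series.values.min():g})"
        )


def convert_destimulant(series: IndicatorSeries) -> IndicatorSeries:
    """Convert a lower-is-better series to a stimulant via ``min(x)/x``.

    The output lies in ``(0, 1]`` and equals 1 exactly at the period(s)
    where the series attains its minimum over the loaded window.
    """
    if series.orientation is not Orientation.DESTIMULANT:
        raise ConversionError(f"series {series.name!r} is not a destimulant")
    _require_positive(series)
    converted = series.values.min() / series.values
    return IndicatorSeries(series.name, converted, Orientation.STIMULANT)


def convert_nominant(series: IndicatorSeries) -> IndicatorSeries:
    """Convert a target-is-best series to a stimulant.

    ``x' = x/c`` for ``x <= c`` and ``c/x`` for ``x > c``; the two branches
    agree at the target, so the map is continuous, equals 1 iff ``x = c``,
    and is strictly increasing below / decreasing above the target.
    """
    if series.orientation is not Orientation.NOMINANT:
        raise ConversionError(f"series {series.name!r} is not a nominant")
    _require_positive(series)
    c = float(series.target)  # type: ignore[arg-type]
    x = series.values
    converted = np.where(x <= c, x / c, c / x)
    return IndicatorSeries(series.name, converted, Orientation.STIMULANT)


@dataclass(frozen=True)
class IndicatorPanel:
    """A set of indicator series on a common period index.

    ``converted`` marks whether orientation harmonisation has been applied;
    converting twice is an error (the destimulant formula is not idempotent).
    """

    periods: tuple
    series: tuple[IndicatorSeries, ...]
    converted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        object.__setattr__(self, "series", tuple(self.series))
        if len(self.series) < 1:
            raise ConversionError("panel must contain at least one series")
        n_periods = len(self.periods)
        if n_periods == 0:
            raise ConversionError("panel must contain at least one period")
        for s in self.series:
            if len(s) != n_periods:
                raise ConversionError(
                    f"series {s.name!r} has {len(s)} values but the panel has {n_periods} periods"
                )
        names = [s.name for s in self.series]
        if len(set(names)) != len(names):
            raise ConversionError("series names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.series]

    @property
    def n_series(self) -> int:
        return len(self.series)

    def values(self) -> np.ndarray:
        """Matrix of shape (n_periods, n_series), columns in panel order."""
        return np.column_stack([s.values for s in self.series])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values(), index=pd.Index(self.periods, name="period"), columns=self.names)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        orientations: dict[str, Orientation | str] | None = None,
        targets: dict[str, float] | None = None,
        converted: bool = False,
    ) -> "IndicatorPanel":
        orientations = orientations or {}
        targets = targets or {}
        series = tuple(
            IndicatorSeries(
                name=str(col),
                values=frame[col].to_numpy(dtype=float),
                orientation=Orientation(orientations.get(str(col), Orientation.STIMULANT)),
                target=targets.get(str(col)),
            )
            for col in frame.columns
        )
        return cls(periods=tuple(frame.index), series=series, converted=converted)


def convert_panel(panel: IndicatorPanel) -> IndicatorPanel:
    """Harmonise every series of a panel to stimulant orientation.

    Stimulants pass through unchanged; destimulants and nominants are
    converted by the per-series rules.  A panel already marked converted
    is rejected.
    """
    if panel.converted:
        raise ConversionError("panel is already converted to stimulants")
    out = []
    for s in panel.series:
        if s.orientation is Orientation.STIMULANT:
            out.append(s)
        elif s.orientation is Orientation.DESTIMULANT:
            out.append(convert_destimulant(s))
        else:
            out.append(convert_nominant(s))
    return IndicatorPanel(periods=panel.periods, series=tuple(out), converted=True)
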
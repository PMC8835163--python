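"""Benchmark-relative composite KPI series.

A composite KPI aggregates the converted (all-stimulant) indicator panel
into a single per-period number, scaled so that the benchmark scores 100:

* **dynamic** — the benchmark is the panel ``base_offset`` periods earlier
  (by default the previous period):
  ``KPI_t = 100 * sum_i w_i * x'_{i,t} / x'_{i,t-1}``;
* **optimistic** — the benchmark is the componentwise best observed value
  ``x_best``; values are <= 100, with equality iff every variable attains
  its maximum in that period;
* **pessimistic** — the benchmark is the componentwise worst value
  ``x_worst``; values are >= 100 analogously.

Values above 100 read as improvement relative to the benchmark, values
below 100 as deterioration.  Benchmarks are computed over the same window
as the evaluated series (current period included) and may be overridden by
an expert-supplied vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConversionError, DegenerateInputError
from .preprocessing import IndicatorPanel

__all__ = [
    "KPISeries",
    "VARIANTS",
    "benchmark_best",
    "benchmark_worst",
    "kpi_dynamic",
    "kpi_vs_benchmark",
    "kpi_optimistic",
    "kpi_pessimistic",
    "interpret",
    "kpi_family",
]

VARIANTS = ("dynamic", "optimistic", "pessimistic")


@dataclass(frozen=True)
class KPISeries:
    """One composite index series plus the metadata that produced it."""

    periods: tuple
    values: np.ndarray
    variant: str
    method: str | None = None
    scheme: str | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.periods) != self.values.size:
            raise ValueError("periods and values length mismatch")

    def label(self) -> str:
        scheme = self.scheme or "uniform"
        if scheme == "RE" and self.p is not None:
            scheme = f"RE({self.p:g})"
        return f"{self.variant}|{self.method or '-'}|{scheme}"

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.periods, name="period"), name=self.label())


def _converted_values(panel: IndicatorPanel) -> np.ndarray:
    if not panel.converted:
        raise ConversionError("panel must be converted to stimulants before benchmarking")
    return panel.values()


def benchmark_best(panel: IndicatorPanel) -> np.ndarray:
    """Componentwise maxima of the converted panel (the best scenario)."""
    return _converted_values(panel).max(axis=0)


def benchmark_worst(panel: IndicatorPanel) -> np.ndarray:
    """Componentwise minima of the converted panel (the worst scenario)."""
    return _converted_values(panel).min(axis=0)


def _check_weights(weights: np.ndarray, n: int) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.size != n:
        raise ValueError(f"{weights.size} weights for {n} variables")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError(f"weights must sum to 1, got {weights.sum():.12f}")
    return weights


def kpi_dynamic(panel: IndicatorPanel, weights: np.ndarray, base_offset: int = 1, **meta) -> KPISeries:
    """Chain-type index against the panel ``base_offset`` periods earlier.

    Undefined for the first ``base_offset`` periods; the series starts at
    ``periods[base_offset]`` and equals 100 wherever the panel is unchanged
    from its base period.
    """
    x = _converted_values(panel)
    if base_offset < 1:
        raise ValueError("base_offset must be >= 1")
    if x.shape[0] <= base_offset:
        raise DegenerateInputError("dynamic KPI needs more periods than the base offset")
    weights = _check_weights(weights, x.shape[1])
    base = x[:-base_offset]
    if np.any(base == 0):
        raise DegenerateInputError("zero value in a base period: dynamic ratio undefined")
    ratios = x[base_offset:] / base
    values = 100.0 * ratios @ weights
    return KPISeries(panel.periods[base_offset:], values, variant="dynamic", **meta)


def kpi_vs_benchmark(panel: IndicatorPanel, weights: np.ndarray, benchmark: np.ndarray, variant: str = "benchmark", **meta) -> KPISeries:
    """Index of each period against a fixed per-variable benchmark vector."""
    x = _converted_values(panel)
    weights = _check_weights(weights, x.shape[1])
    benchmark = np.asarray(benchmark, dtype=float)
    if benchmark.size != x.shape[1]:
        raise ValueError(f"{benchmark.size} benchmark components for {x.shape[1]} variables")
    if np.any(benchmark <= 0):
        raise DegenerateInputError("benchmark components must be strictly positive")
    values = 100.0 * (x / benchmark) @ weights
    return KPISeries(panel.periods, values, variant=variant, **meta)


def kpi_optimistic(panel: IndicatorPanel, weights: np.ndarray, **meta) -> KPISeries:
    return kpi_vs_benchmark(panel, weights, benchmark_best(panel), variant="optimistic", **meta)


def kpi_pessimistic(panel: IndicatorPanel, weights: np.ndarray, **meta) -> KPISeries:
    return kpi_vs_benchmark(panel, weights, benchmark_worst(panel), variant="pessimistic", **meta)


def interpret(series: KPISeries, tol: float = 1e-9) -> list[str]:
    """Classify each period as improvement / deterioration / neutral.

    Dynamic series are read against the benchmark level 100 (they already
    measure change); fixed-benchmark series are read as the direction of
    change from the previous period, with the first period neutral.
    """
    if series.variant == "dynamic":
        deltas = series.values - 100.0
    else:
        deltas = np.concatenate([[0.0], np.diff(series.values)])
    out = []
    for d in deltas:
        if d > tol:
            out.append("improvement")
        elif d < -tol:
            out.append("deterioration")
        else:
            out.append("neutral")
    return out


def kpi_family(
    panel: IndicatorPanel,
    weights: pd.DataFrame,
    variants: tuple[str, ...] = VARIANTS,
    include_uniform: bool = True,
) -> pd.DataFrame:
    """Compute the full family of KPI series over a weight table.

    ``weights`` is the frame produced by :func:`kpibench.weighting.weight_table`
    (rows indexed by (scheme, method, p), one column per panel variable, in
    panel order).  ``include_uniform`` adds an unweighted row (all weights
    1/n) per variant.  Returns a long frame with columns
    ``period, variant, method, scheme, p, value``.
    """
    if list(weights.columns) != panel.names:
        raise ValueError("weight table columns must match panel variables in order")
    rows = list(weights.iterrows())
    if include_uniform:
        n = panel.n_series
        uniform = pd.Series(np.full(n, 1.0 / n), index=weights.columns)
        rows.append((("uniform", "-", np.nan), uniform))
    records = []
    for variant in variants:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        for (scheme, method, p), w in rows:
            meta = dict(scheme=scheme, method=method, p=None if pd.isna(p) else float(p))
            if variant == "dynamic":
                series = kpi_dynamic(panel, w.to_numpy(), **meta)
            elif variant == "optimistic":
                series = kpi_optimistic(panel, w.to_numpy(), **meta)
            else:
                series = kpi_pessimistic(panel, w.to_numpy(), **meta)
            for period, value in zip(series.periods, series.values):
                records.append(
                    {"period": period, "variant": variant, "method": method,
                     "scheme": scheme, "p": meta["p"], "value": value}
                )
    return pd.DataFrame.from_records(records)
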
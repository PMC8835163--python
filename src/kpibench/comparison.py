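"""Similarity analytics for families of KPI series.

The index families produced by :func:`kpibench.kpi.kpi_family` differ only
in weighting choices; this module quantifies how much those choices matter:

* max-standardisation ``KPI'_t = KPI_t / max_t KPI_t`` maps every series
  into ``(0, 1]`` while preserving its internal ordering;
* Euclidean distances between standardised series;
* Pearson and Spearman correlation matrices with a significance mask at a
  configurable level (default 0.05);
* direction-consistency counts — how many series of the family agree on
  improvement vs the previous period;
* nonparametric median-difference tests between groups of series values
  (Mood's median test by default, Kruskal-Wallis as an option).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "standardise",
    "euclidean_distance",
    "trim_common_window",
    "distance_matrix",
    "correlation_matrix",
    "direction_consistency",
    "MedianTestResult",
    "median_difference_test",
    "median_tests_by",
    "family_to_wide",
]


def standardise(values: np.ndarray) -> np.ndarray:
    """Divide a positive series by its maximum; output in (0, 1], max = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("cannot standardise an empty series")
    if np.any(values <= 0):
        raise DegenerateInputError("standardisation requires strictly positive values")
    return values / values.max()


def euclidean_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("series must have equal length")
    return float(np.linalg.norm(s1 - s2))


def family_to_wide(family: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long KPI family frame to periods x labelled series."""
    labels = family.apply(
        lambda r: f"{r['variant']}|{r['method']}|"
        + (f"{r['scheme']}({r['p']:g})" if pd.notna(r.get("p")) and r["scheme"] == "RE" else str(r["scheme"])),
        axis=1,
    )
    wide = family.assign(label=labels).pivot(index="period", columns="label", values="value")
    return wide


def trim_common_window(wide: pd.DataFrame) -> pd.DataFrame:
    """Drop periods where any series is missing, so all have equal length.

    The dynamic variant starts one period later than the fixed-benchmark
    variants; trimming aligns the family on the shared window.
    """
    return wide.dropna(axis=0, how="any")


def distance_matrix(wide: pd.DataFrame, standardised: bool = True) -> pd.DataFrame:
    """Pairwise Euclidean distances between (standardised) series."""
    data = wide.to_numpy(dtype=float)
    if standardised:
        data = np.column_stack([standardise(data[:, j]) for j in range(data.shape[1])])
    diff = data[:, :, None] - data[:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=0))
    return pd.DataFrame(d, index=wide.columns, columns=wide.columns)


def _spearman_exact_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n).

    Enumerates all pairings of the rank vectors; feasible for n < 10.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    r_obs = np.corrcoef(rx, ry)[0, 1]
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    py_c = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (py_c ** 2).sum(axis=1))
    r_all = (py_c @ rx_c) / denom
    return float(np.mean(np.abs(r_all) >= np.abs(r_obs) - 1e-12))


def _pair_correlation(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant series: correlation undefined, reported as NaN", stacklevel=3)
        return math.nan, math.nan
    if kind == "pearson":
        r, p = stats.pearsonr(x, y)
    elif kind == "spearman":
        r, p = stats.spearmanr(x, y)
        if x.size < 10:
            p = _spearman_exact_pvalue(x, y)
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    return float(r), float(p)


def correlation_matrix(
    wide: pd.DataFrame, kind: str = "pearson", alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix plus a mask of statistically insignificant cells.

    Returns ``(corr, insignificant)``: ``corr`` is symmetric with unit
    diagonal; ``insignificant`` is True where the two-sided p-value is
    >= ``alpha`` (the diagonal is always significant).  Constant series
    yield NaN correlations (flagged by a warning), never a silent zero.
    """
    if wide.shape[0] < 3:
        raise DegenerateInputError("correlation needs at least 3 common periods")
    cols = list(wide.columns)
    m = len(cols)
    corr = np.eye(m)
    insig = np.zeros((m, m), dtype=bool)
    data = wide.to_numpy(dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            r, p = _pair_correlation(data[:, i], data[:, j], kind)
            corr[i, j] = corr[j, i] = r
            insig[i, j] = insig[j, i] = not (p < alpha)
    return (
        pd.DataFrame(corr, index=cols, columns=cols),
        pd.DataFrame(insig, index=cols, columns=cols),
    )


def direction_consistency(wide: pd.DataFrame) -> pd.DataFrame:
    """Per-period counts of series improving / deteriorating vs the
    previous period (first period omitted)."""
    diffs = wide.diff().iloc[1:]
    return pd.DataFrame(
        {
            "improving": (diffs > 0).sum(axis=1),
            "deteriorating": (diffs < 0).sum(axis=1),
            "unchanged": (diffs == 0).sum(axis=1),
        }
    )


@dataclass(frozen=True)
class MedianTestResult:
    statistic: float
    p_value: float
    significant: bool
    test: str
    alpha: float


def median_difference_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    test: str = "mood",
) -> MedianTestResult:
    """Two-sided nonparametric test of equal medians between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateInputError("median test needs at least 3 values per group")
    if test == "mood":
        res = stats.median_test(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal":
        statistic, p = (float(v) for v in stats.kruskal(a, b))
    else:
        raise ValueError(f"unknown median test {test!r}")
    return MedianTestResult(statistic, p, bool(p < alpha), test, alpha)


def median_tests_by(
    family: pd.DataFrame, by: str, alpha: float = 0.05, test: str = "mood"
) -> pd.DataFrame:
    """Pairwise median-difference tests between groups of a KPI family.

    ``by`` is one of ``variant``, ``method``, ``scheme``; each group pools
    all values of the family's series sharing that key.
    """
    if by not in {"variant", "method", "scheme"}:
        raise ValueError("grouping must be one of variant / method / scheme")
    groups = {k: g["value"].to_numpy() for k, g in family.groupby(by) if k != "-"}
    records = []
    for (ka, va), (kb, vb) in itertools.combinations(sorted(groups.items()), 2):
        res = median_difference_test(va, vb, alpha=alpha, test=test)
        records.append(
            {"group_a": ka, "group_b": kb, "statistic": res.statistic,
             "p_value": res.p_value, "significant": res.significant}
        )
    return pd.DataFrame.from_records(records)
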
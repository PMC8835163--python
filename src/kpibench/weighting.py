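"""Importance ranking and surrogate weight elicitation.

Two score functions condense the DEMATEL indicators (t+, t-) into a single
importance score per variable:

* ``BD`` — the Euclidean norm ``sqrt(t+^2 + t-^2)``, normalised to sum 1;
* ``K``  — the half-sum ``(t+ + t-) / 2``, normalised to sum 1.

Variables are ranked by a score (method ``BD`` or ``K``) or by prominence
alone (method ``T+``); rank 1 is the most significant variable, and ties
receive fractional (average) ranks.  From a rank vector, four closed-form
surrogate-weight schemes produce a weight vector summing to 1:

=====  =====================================================
RS     rank sum        ``w_j = 2 (n + 1 - r_j) / (n (n + 1))``
RE(p)  rank exponent   ``w_j = (n + 1 - r_j)^p / sum_k (...)^p``
RR     rank reciprocal ``w_j = (1 / r_j) / sum_k (1 / r_k)``
ROC    rank centroid   ``w_j = (1/n) sum_{k: r_k >= r_j} (1 / r_k)``
=====  =====================================================

RE(1) coincides with RS, and RE(p -> 0) tends to uniform weights.  The BD
and K scores can also be used directly as weights ("direct" schemes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dematel import InfluenceIndicators
from .errors import DegenerateInputError

__all__ = [
    "RANK_METHODS",
    "DEFAULT_P_GRID",
    "score_bd",
    "score_k",
    "ranks_from_scores",
    "rank_variables",
    "weights_rank_sum",
    "weights_rank_exponent",
    "weights_rank_reciprocal",
    "weights_rank_centroid",
    "weights_direct",
    "weight_table",
]

RANK_METHODS = ("T+", "BD", "K")

#: Rank-exponent powers swept by default (p = 1 duplicates rank sum).
DEFAULT_P_GRID = (0.5, 1.5, 2.0, 2.5, 3.0, 3.5)


def score_bd(indicators: InfluenceIndicators) -> np.ndarray:
    """Normalised Euclidean norm of (t+, t-) per variable."""
    norms = np.hypot(indicators.t_plus, indicators.t_minus)
    total = norms.sum()
    if total <= 0:
        raise DegenerateInputError("BD scores undefined: all influence indicators are zero")
    return norms / total


def score_k(indicators: InfluenceIndicators) -> np.ndarray:
    """Normalised half-sum (t+ + t-) / 2 per variable.

    A strong net receiver (t- < -t+) yields a negative score; such scores
    are passed through with a warning rather than clipped.
    """
    half_sums = (indicators.t_plus + indicators.t_minus) / 2.0
    total = half_sums.sum()
    if total <= 0:
        raise DegenerateInputError("K scores undefined: non-positive half-sum total")
    scores = half_sums / total
    if np.any(scores < 0):
        warnings.warn("negative K score(s): some variable has t- < -t+", stacklevel=2)
    return scores


def ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Rank variables by score, rank 1 = highest score, ties averaged."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise DegenerateInputError("ranking needs at least two variables")
    return rankdata(-scores, method="average")

def rank_variables(indicators: InfluenceIndicators, method: str = "BD") -> np.ndarray:
    """Rank by prominence alone (``T+``) or by a combined score (``BD``/``K``)."""
    if method == "T+":
        return ranks_from_scores(indicators.t_plus)
    if method == "BD":
        return ranks_from_scores(score_bd(indicators))
    if method == "K":
        return ranks_from_scores(score_k(indicators))
    raise ValueError(f"unknown ranking method {method!r}; expected one of {RANK_METHODS}")


def _check_ranks(ranks: np.ndarray) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=float)
    n = ranks.size
    if n < 1:
        raise DegenerateInputError("empty rank vector")
    if np.any(ranks < 1) or np.any(ranks > n):
        raise DegenerateInputError("ranks must lie in [1, n]")
    return ranks


def _normalized(weights: np.ndarray) -> np.ndarray:
    # exact for untied rank permutations; with average ties the closed forms
    # need an explicit renormalisation to keep sum(w) = 1
    return weights / weights.sum()


def weights_rank_sum(ranks: np.ndarray) -> np.ndarray:
    ranks = _check_ranks(ranks)
    n = ranks.size
    return _normalized(2.0 * (n + 1 - ranks) / (n * (n + 1)))


def weights_rank_exponent(ranks: np.ndarray, p: float) -> np.ndarray:
    if not (p > 0 and np.isfinite(p)):
        raise ValueError(f"rank-exponent power must be positive, got {p}")
    ranks = _check_ranks(ranks)
    n = ranks.size
    return _normalized((n + 1 - ranks) ** p)


def weights_rank_reciprocal(ranks: np.ndarray) -> np.ndarray:
    ranks = _check_ranks(ranks)
    return _normalized(1.0 / ranks)


def weights_rank_centroid(ranks: np.ndarray) -> np.ndarray:
    """Rank-order-centroid weights: each variable averages the reciprocal
    ranks of itself and everything ranked at or below it."""
    ranks = _check_ranks(ranks)
    n = ranks.size
    weights = np.array([(1.0 / ranks[ranks >= r]).sum() / n for r in ranks])
    return _normalized(weights)


def weights_direct(scores: np.ndarray) -> np.ndarray:
    """Use importance scores directly as weights (renormalised defensively)."""
    scores = np.asarray(scores, dtype=float)
    total = scores.sum()
    if total <= 0:
        raise DegenerateInputError("direct weights undefined: non-positive score total")
    return scores / total


def weight_table(
    indicators: InfluenceIndicators,
    methods: tuple[str, ...] = RANK_METHODS,
    p_grid: tuple[float, ...] = DEFAULT_P_GRID,
) -> pd.DataFrame:
    """All (scheme, ranking-method) weight rows for one indicator family.

    Returns a frame indexed by ``(scheme, method, p)`` with one column per
    variable: RS/RE(p)/RR/ROC rows for every ranking method, plus the two
    direct rows (scheme ``direct``, methods ``BD`` and ``K``) which do not
    depend on a ranking.
    """
    rows: dict[tuple[str, str, float], np.ndarray] = {}
    for method in methods:
        ranks = rank_variables(indicators, method)
        rows[("RS", method, np.nan)] = weights_rank_sum(ranks)
        for p in p_grid:
            rows[("RE", method, p)] = weights_rank_exponent(ranks, p)
        rows[("RR", method, np.nan)] = weights_rank_reciprocal(ranks)
        rows[("ROC", method, np.nan)] = weights_rank_centroid(ranks)
    rows[("direct", "BD", np.nan)] = weights_direct(score_bd(indicators))
    rows[("direct", "K", np.nan)] = weights_direct(score_k(indicators))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(indicators.labels))
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["scheme", "method", "p"])
    return frame
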
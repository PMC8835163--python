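"""Weight elicitation: published weight-table reproduction plus scheme properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kpibench import weighting
from kpibench.dematel import InfluenceIndicators
from kpibench.errors import DegenerateInputError
from kpibench.weighting import (
    DEFAULT_P_GRID,
    rank_variables,
    ranks_from_scores,
    score_bd,
    score_k,
    weight_table,
    weights_direct,
    weights_rank_centroid,
    weights_rank_exponent,
    weights_rank_reciprocal,
    weights_rank_sum,
)

# Published reference weights for the two five-variable families
# (sociological S1..S5 and economic E1..E5), one row per (scheme, method).
REFERENCE_WEIGHTS = {
    ("RS", "BD"): ([0.0667, 0.1333, 0.2667, 0.3333, 0.2000],
                   [0.2667, 0.2000, 0.1333, 0.3333, 0.066667]),
    ("RE(0.5)", "BD"): ([0.1193, 0.1687, 0.2386, 0.2668, 0.2066],
                        [0.2386, 0.2066, 0.1687, 0.2668, 0.119299]),
    ("RE(1.5)", "BD"): ([0.0355, 0.1003, 0.2836, 0.3964, 0.1842],
                        [0.2836, 0.1842, 0.1003, 0.3964, 0.035455]),
    ("RE(2)", "BD"): ([0.0182, 0.0727, 0.2909, 0.4545, 0.1636],
                      [0.2909, 0.1636, 0.0727, 0.4545, 0.018182]),
    ("RE(2.5)", "BD"): ([0.0091, 0.0514, 0.2905, 0.5075, 0.1415],
                        [0.2905, 0.1415, 0.0514, 0.5075, 0.009079]),
    ("RE(3)", "BD"): ([0.0044, 0.0356, 0.2844, 0.5556, 0.1200],
                      [0.2844, 0.1200, 0.0356, 0.5556, 0.004444]),
    ("RE(3.5)", "BD"): ([0.0021, 0.0242, 0.2743, 0.5990, 0.1002],
                        [0.2743, 0.1002, 0.0242, 0.5990, 0.002143]),
    ("RR", "BD"): ([0.0876, 0.1095, 0.2190, 0.4380, 0.1460],
                   [0.2190, 0.1460, 0.1095, 0.4380, 0.087591]),
    ("ROC", "BD"): ([0.0400, 0.0900, 0.2567, 0.4567, 0.1567],
                    [0.2567, 0.1567, 0.0900, 0.4567, 0.04]),
    ("RS", "K"): ([0.2000, 0.1333, 0.3333, 0.2667, 0.0667],
                  [0.2000, 0.2667, 0.1333, 0.3333, 0.066667]),
    ("RE(0.5)", "K"): ([0.2066, 0.1687, 0.2668, 0.2386, 0.1193],
                       [0.2066, 0.2386, 0.1687, 0.2668, 0.119299]),
    ("RE(1.5)", "K"): ([0.1842, 0.1003, 0.3964, 0.2836, 0.0355],
                       [0.1842, 0.2836, 0.1003, 0.3964, 0.035455]),
    ("RE(2)", "K"): ([0.1636, 0.0727, 0.4545, 0.2909, 0.0182],
                     [0.1636, 0.2909, 0.0727, 0.4545, 0.018182]),
    ("RE(2.5)", "K"): ([0.1415, 0.0514, 0.5075, 0.2905, 0.0091],
                       [0.1415, 0.2905, 0.0514, 0.5075, 0.009079]),
    ("RE(3)", "K"): ([0.1200, 0.0356, 0.5556, 0.2844, 0.0044],
                     [0.1200, 0.2844, 0.0356, 0.5556, 0.004444]),
    ("RE(3.5)", "K"): ([0.1002, 0.0242, 0.5990, 0.2743, 0.0021],
                       [0.1002, 0.2743, 0.0242, 0.5990, 0.002143]),
    ("RR", "K"): ([0.1460, 0.1095, 0.4380, 0.2190, 0.0876],
                  [0.1460, 0.2190, 0.1095, 0.4380, 0.087591]),
    ("ROC", "K"): ([0.1567, 0.0900, 0.4567, 0.2567, 0.0400],
                   [0.1567, 0.2567, 0.0900, 0.4567, 0.04]),
    ("direct", "BD"): ([0.1795, 0.1891, 0.1991, 0.2359, 0.1964],
                       [0.2229, 0.2175, 0.1975, 0.2278, 0.13431]),
    ("direct", "K"): ([0.1894, 0.1891, 0.2277, 0.2072, 0.1866],
                      [0.2206, 0.2265, 0.2039, 0.2304, 0.119]),
}


def _scheme_key(scheme, p):
    if scheme == "RE":
        return f"RE({p:g})"
    return scheme


rank_permutations = st.permutations(list(range(1, 6)))


class TestScores:
    def test_bd_scores_match_reference(self, economic_indicators, social_indicators):
        np.testing.assert_allclose(score_bd(economic_indicators),
                                   REFERENCE_WEIGHTS[("direct", "BD")][1], atol=1e-3)
        np.testing.assert_allclose(score_bd(social_indicators),
                                   REFERENCE_WEIGHTS[("direct", "BD")][0], atol=1e-3)

    def test_k_scores_match_reference(self, economic_indicators, social_indicators):
        np.testing.assert_allclose(score_k(economic_indicators),
                                   REFERENCE_WEIGHTS[("direct", "K")][1], atol=1e-3)
        np.testing.assert_allclose(score_k(social_indicators),
                                   REFERENCE_WEIGHTS[("direct", "K")][0], atol=1e-3)

    def test_zero_relation_reduces_both_to_prominence_shares(self):
        ind = InfluenceIndicators(("a", "b"), np.array([3.0, 1.0]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(score_bd(ind), [0.75, 0.25])
        np.testing.assert_allclose(score_k(ind), [0.75, 0.25])

    def test_single_dominant_variable(self):
        ind = InfluenceIndicators(("a", "b"), np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(score_bd(ind), [1.0, 0.0])

    def test_negative_k_score_warns(self):
        ind = InfluenceIndicators(("a", "b"), np.array([1.0, 5.0]), np.array([-2.0, 1.0]))
        with pytest.warns(UserWarning, match="negative K score"):
            score_k(ind)

    def test_all_zero_indicators_rejected(self):
        ind = InfluenceIndicators(("a", "b"), np.zeros(2), np.zeros(2))
        with pytest.raises(DegenerateInputError):
            score_bd(ind)


class TestRanking:
    def test_economic_prominence_ranks(self, economic_indicators):
        ranks = rank_variables(economic_indicators, "T+")
        # employment most significant, budget deficit least
        np.testing.assert_array_equal(ranks, [2, 3, 4, 1, 5])

    def test_prominence_and_bd_ranks_coincide_on_both_families(
        self, economic_indicators, social_indicators
    ):
        for ind in (economic_indicators, social_indicators):
            np.testing.assert_array_equal(
                rank_variables(ind, "T+"), rank_variables(ind, "BD")
            )

    def test_ties_get_average_ranks(self):
        ranks = ranks_from_scores(np.array([0.3, 0.3, 0.3]))
        np.testing.assert_array_equal(ranks, [2, 2, 2])

    def test_unknown_method_rejected(self, economic_indicators):
        with pytest.raises(ValueError):
            rank_variables(economic_indicators, "XYZ")


class TestReferenceWeightTable:
    @pytest.mark.parametrize("scheme_method", sorted(REFERENCE_WEIGHTS), ids=str)
    def test_full_reproduction(self, scheme_method, economic_indicators, social_indicators):
        """Every published (scheme, method) weight row is matched to +/-0.001."""
        scheme, method = scheme_method
        soc_expected, econ_expected = REFERENCE_WEIGHTS[scheme_method]
        for ind, expected in ((social_indicators, soc_expected),
                              (economic_indicators, econ_expected)):
            table = weight_table(ind)
            labels = {(_scheme_key(s, p), m): row
                      for (s, m, p), row in table.iterrows()}
            np.testing.assert_allclose(labels[(scheme, method)].to_numpy(), expected,
                                       atol=1e-3)

    def test_t_plus_rows_equal_bd_rows(self, economic_indicators, social_indicators):
        for ind in (economic_indicators, social_indicators):
            table = weight_table(ind)
            sorted_table = table.sort_index()
            for scheme in ("RS", "RR", "ROC"):
                np.testing.assert_allclose(
                    sorted_table.loc[(scheme, "T+")].to_numpy(),
                    sorted_table.loc[(scheme, "BD")].to_numpy(),
                )


class TestSchemeFormulas:
    @pytest.mark.parametrize(
        "func, rank1_expected",
        [
            (weights_rank_sum, 1 / 3),
            (lambda r: weights_rank_exponent(r, 2.0), 25 / 55),
            (weights_rank_reciprocal, (1 / 1) / sum(1 / r for r in range(1, 6))),
            (weights_rank_centroid, sum(1 / r for r in range(1, 6)) / 5),
        ],
    )
    def test_top_rank_weight_n5(self, func, rank1_expected):
        w = func(np.array([1, 2, 3, 4, 5]))
        assert w[0] == pytest.approx(rank1_expected, abs=1e-12)

    def test_rank_sum_single_variable(self):
        assert weights_rank_sum(np.array([1])) == pytest.approx(1.0)

    def test_rank_reciprocal_two_variables(self):
        np.testing.assert_allclose(weights_rank_reciprocal(np.array([1, 2])), [2 / 3, 1 / 3])

    @given(ranks=rank_permutations)
    @settings(max_examples=50, derandomize=True)
    def test_rank_exponent_p1_equals_rank_sum(self, ranks):
        ranks = np.asarray(ranks, float)
        np.testing.assert_allclose(
            weights_rank_exponent(ranks, 1.0), weights_rank_sum(ranks), atol=1e-15
        )

    def test_rank_exponent_small_p_approaches_uniform(self):
        w = weights_rank_exponent(np.array([1, 2, 3, 4, 5]), 1e-9)
        np.testing.assert_allclose(w, 0.2, atol=1e-8)

    @pytest.mark.parametrize("p", [0, -1.5])
    def test_rank_exponent_requires_positive_p(self, p):
        with pytest.raises(ValueError):
            weights_rank_exponent(np.array([1, 2]), p)

    @given(ranks=rank_permutations, scheme=st.sampled_from(["RS", "RE", "RR", "ROC"]),
           p=st.sampled_from(DEFAULT_P_GRID))
    @settings(max_examples=120, derandomize=True)
    def test_weights_sum_to_one_and_decrease_in_rank(self, ranks, scheme, p):
        ranks = np.asarray(ranks, float)
        w = {
            "RS": weights_rank_sum,
            "RE": lambda r: weights_rank_exponent(r, p),
            "RR": weights_rank_reciprocal,
            "ROC": weights_rank_centroid,
        }[scheme](ranks)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)
        order = np.argsort(ranks)
        assert np.all(np.diff(w[order]) < 0)  # strictly decreasing in rank number

    def test_direct_weights_normalise_scores(self):
        np.testing.assert_allclose(weights_direct(np.array([2.0, 2.0])), [0.5, 0.5])
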
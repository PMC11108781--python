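"""Exact binomial, McNemar, paired one-sided tests and the gatekeeper."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from armtrial import (
    exact_binomial_test,
    mcnemar_exact,
    paired_one_sided,
    run_hierarchy,
    summarize_change,
)


def binomial_upper_tail_oracle(successes, n, p0):
    """Brute-force pmf summation."""
    return sum(
        comb(n, k, exact=True) * p0**k * (1 - p0) ** (n - k)
        for k in range(successes, n + 1)
    )


def signed_rank_upper_tail_oracle(d):
    """Exact one-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    hits = total = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        w = ranks[np.array(signs) > 0].sum()
        total += 1
        hits += w >= w_obs - 1e-12
    return hits / total


class TestExactBinomial:
    def test_primary_endpoint_significance(self):
        res = exact_binomial_test(43, 60, 0.5)
        assert res.p_value < 0.001
        assert res.p_value == pytest.approx(binomial_upper_tail_oracle(43, 60, 0.5))

    @pytest.mark.parametrize("n", [5, 12, 31])
    def test_all_successes_closed_form(self, n):
        assert exact_binomial_test(n, n, 0.5).p_value == pytest.approx(0.5**n)

    def test_zero_successes_whole_support(self):
        assert exact_binomial_test(0, 40, 0.3).p_value == pytest.approx(1.0)

    def test_strictly_decreasing_in_successes(self):
        ps = [exact_binomial_test(k, 25, 0.4).p_value for k in range(26)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for k in range(n + 1):
                assert exact_binomial_test(k, n, 0.5).p_value == pytest.approx(
                    binomial_upper_tail_oracle(k, n, 0.5), rel=1e-12
                )

    @pytest.mark.parametrize("successes,n,p0", [(-1, 10, 0.5), (11, 10, 0.5), (5, 10, 0.0)])
    def test_invalid_inputs_rejected(self, successes, n, p0):
        with pytest.raises(ValueError):
            exact_binomial_test(successes, n, p0)


class TestMcnemar:
    def test_trial_conversion_discordants_round_to_printed_value(self):
        assert round(mcnemar_exact(4, 16), 3) == 0.012

    def test_symmetric_discordants_give_one(self):
        assert mcnemar_exact(7, 7) == 1.0

    def test_one_sided_extreme_closed_form(self):
        assert mcnemar_exact(0, 8) == pytest.approx(2 * 0.5**8)

    def test_symmetry_in_arguments(self):
        for b, c in [(3, 9), (0, 5), (12, 2)]:
            assert mcnemar_exact(b, c) == mcnemar_exact(c, b)

    def test_agrees_with_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(4, 16), (2, 10), (5, 5), (0, 7)]:
            table = [[30, b], [c, 20]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected)

    def test_no_discordants_returns_one(self):
        assert mcnemar_exact(0, 0) == 1.0


class TestPropertyInvariants:
    @settings(derandomize=True, max_examples=80)
    @given(n=st.integers(1, 150), k=st.integers(0, 150),
           p0=st.floats(0.05, 0.95))
    def test_binomial_p_is_valid_and_decreasing_in_successes(self, n, k, p0):
        k = min(k, n)
        p = exact_binomial_test(k, n, p0).p_value
        assert 0.0 < p <= 1.0
        if k < n:
            # strict decrease mathematically; at the far lower tail the two
            # values can collapse to 1.0 in double precision
            assert exact_binomial_test(k + 1, n, p0).p_value <= p

    @settings(derandomize=True, max_examples=80)
    @given(b=st.integers(0, 40), c=st.integers(0, 40))
    def test_mcnemar_symmetric_valid_and_maximal_at_balance(self, b, c):
        p = mcnemar_exact(b, c)
        assert 0.0 < p <= 1.0
        assert p == mcnemar_exact(c, b)
        if b + c > 0:
            # rebalancing the same number of discordants never lowers p
            m = b + c
            assert mcnemar_exact(m // 2, m - m // 2) >= p

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    def test_ci90_contains_the_mean(self, values):
        mean, _, (lo, hi) = summarize_change(values)
        assert lo - 1e-9 <= mean <= hi + 1e-9


class TestSummarizeChange:
    def test_constant_vector_degenerate_ci(self):
        mean, sd, ci = summarize_change([3.0, 3.0, 3.0])
        assert (mean, sd) == (3.0, 0.0)
        assert ci == (3.0, 3.0)

    def test_one_two_three_closed_form(self):
        mean, sd, ci = summarize_change([1.0, 2.0, 3.0])
        tq = sps.t.ppf(0.95, 2)
        assert (mean, sd) == (2.0, 1.0)
        assert ci == pytest.approx((2 - tq / math.sqrt(3), 2 + tq / math.sqrt(3)))

    def test_antisymmetric_vector_mean_zero(self):
        mean, _, _ = summarize_change([-4.2, 4.2])
        assert mean == pytest.approx(0.0)


class TestPairedOneSided:
    def test_null_p_values_center_on_half(self):
        rng = np.random.default_rng(5)
        ps = [
            paired_one_sided(rng.normal(0, 1, 200)).p_value for _ in range(200)
        ]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.07)

    def test_identical_positive_differences_exact_tail(self):
        res = paired_one_sided([2.0] * 6)
        assert res.method == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(0.5**6)

    def test_frozen_enumeration_example(self):
        # exact signed-rank tail for (1,2,3,4,5,-1), all 2^6 sign patterns
        res = paired_one_sided([1, 2, 3, 4, 5, -1.0], normality_alpha=1.0)
        assert res.method == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(0.046875)

    def test_wilcoxon_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for n in range(4, 13):
            d = rng.normal(0.5, 1.0, n)
            res = paired_one_sided(d, normality_alpha=1.0)  # force wilcoxon
            assert res.method == "wilcoxon_signed_rank"
            assert res.p_value == pytest.approx(signed_rank_upper_tail_oracle(d))

    def test_normality_gate_chooses_t_for_gaussian(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1, 1, 60)
        res = paired_one_sided(d)
        assert res.method == "paired_t"
        assert res.p_value == pytest.approx(
            sps.ttest_1samp(d, 0.0, alternative="greater").pvalue
        )

    def test_normality_gate_chooses_wilcoxon_for_heavy_skew(self):
        rng = np.random.default_rng(1)
        d = np.exp(rng.normal(0, 1, 80)) - 0.5
        res = paired_one_sided(d)
        assert res.normality_p < 0.05
        assert res.method == "wilcoxon_signed_rank"

    def test_lower_is_better_direction_reverses_alternative(self):
        d = np.array([-2.0, -1.5, -2.5, -1.0, -3.0, -2.2, -0.5, -1.8])
        worse = paired_one_sided(d, direction="higher_is_better")
        better = paired_one_sided(d, direction="lower_is_better")
        assert better.p_value < 0.05 < worse.p_value
        assert better.mean_diff == pytest.approx(d.mean())

    def test_ci90_is_two_sided_t_interval(self):
        rng = np.random.default_rng(2)
        d = rng.normal(2, 1, 40)
        res = paired_one_sided(d)
        se = d.std(ddof=1) / math.sqrt(40)
        tq = sps.t.ppf(0.95, 39)
        assert res.ci90 == pytest.approx((d.mean() - tq * se, d.mean() + tq * se))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_one_sided([1.0, 2.0])


class TestHierarchy:
    def _diffs(self, effects, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return {
            name: rng.normal(mu, 1.0, n) for name, mu in effects.items()
        }

    def test_halt_at_first_failure_leaves_rest_untested(self):
        order = ["a", "b", "c", "d"]
        diffs = self._diffs({"a": 2.0, "b": 2.0, "c": 0.0, "d": 2.0})
        report = run_hierarchy(order, diffs)
        assert report.tested == [True, True, True, False]
        assert report.passed == [True, True, False, False]
        assert report.halt_index == 2
        assert math.isnan(report.as_rows()[3]["p_value"] or float("nan"))

    def test_all_strong_effects_pass_without_halt(self):
        order = ["a", "b", "c"]
        report = run_hierarchy(order, self._diffs({"a": 5, "b": 5, "c": 5}))
        assert report.halt_index is None
        assert all(report.passed)

    def test_first_endpoint_failure_tests_exactly_one(self):
        report = run_hierarchy(["a", "b"], self._diffs({"a": 0.0, "b": 5.0}))
        assert report.tested == [True, False]
        assert report.halt_index == 0

    def test_tested_set_is_a_prefix(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            effects = {f"e{i}": float(rng.choice([0.0, 2.0])) for i in range(6)}
            report = run_hierarchy(list(effects), self._diffs(effects, seed=seed))
            # once False, stays False
            assert report.tested == sorted(report.tested, reverse=True)

    def test_post_halt_permutation_preserves_pre_halt_results(self):
        order = ["a", "b", "c", "d", "e"]
        diffs = self._diffs({"a": 3.0, "b": 0.0, "c": 1.0, "d": 2.0, "e": 0.5})
        r1 = run_hierarchy(order, diffs)
        r2 = run_hierarchy(["a", "b", "e", "d", "c"], diffs)
        assert r1.halt_index == r2.halt_index == 1
        for i in range(2):
            assert r1.results[i].p_value == r2.results[i].p_value

    def test_insufficient_data_endpoint_halts(self):
        diffs = self._diffs({"a": 5.0})
        diffs["b"] = np.array([1.0])
        report = run_hierarchy(["a", "b", "c"], diffs)
        assert report.tested == [True, True, False]
        assert report.halt_index == 1
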
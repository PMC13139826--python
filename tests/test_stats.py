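"""Group-level inference: Welch t, power, FDR, group models, matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddtask import (
    SummaryStats, bh_fdr, binomial_group_model, covariate_association,
    gaussian_group_model, match_pairs, power_two_sample, welch_t,
)
from ddtask.errors import (
    InsufficientDataError, SeparationError, ValidationError,
)


class TestWelchT:
    def test_identical_groups(self):
        a = SummaryStats(5.0, 1.0, 30)
        t, df, p = welch_t(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_bmi_summaries(self):
        # published demographic table, BMI row (controls vs patients, n=80)
        t, df, p = welch_t(SummaryStats(20.89, 2.10, 80),
                           SummaryStats(14.66, 1.42, 80))
        assert t == pytest.approx(22.00, abs=0.1)
        assert df == pytest.approx(138.78, abs=0.5)
        assert p < 1e-10

    def test_age_summaries_satterthwaite_df(self):
        t, df, p = welch_t(SummaryStats(16.27, 2.51, 80),
                           SummaryStats(16.26, 2.48, 80))
        assert df == pytest.approx(157.98, abs=0.5)
        assert p > 0.9

    def test_antisymmetric(self):
        a, b = SummaryStats(5.0, 1.2, 20), SummaryStats(4.0, 2.0, 25)
        ta, dfa, _ = welch_t(a, b)
        tb, dfb, _ = welch_t(b, a)
        assert ta == pytest.approx(-tb)
        assert dfa == pytest.approx(dfb)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValidationError):
            welch_t(SummaryStats(1.0, 0.0, 10), SummaryStats(1.0, 0.0, 10))


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample(0.0, 50, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    @pytest.mark.parametrize("d,expect", [(0.5, 0.93), (0.3, 0.60), (0.2, 0.35)])
    def test_published_power_statements(self, d, expect):
        # one-sided two-sample t-test, n = 80 per group, alpha = .05
        assert power_two_sample(d, 80, 0.05, "one") == pytest.approx(expect, abs=0.005)

    def test_monotone_in_effect_and_n(self):
        powers_d = [power_two_sample(d, 40) for d in (0.1, 0.3, 0.5, 0.8)]
        assert all(a < b for a, b in zip(powers_d, powers_d[1:]))
        powers_n = [power_two_sample(0.4, n) for n in (10, 40, 160)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_two_sided_less_powerful(self):
        assert power_two_sample(0.4, 50, sided="two") < power_two_sample(0.4, 50, sided="one")

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            power_two_sample(0.5, 50, alpha=1.5)


class TestFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_hand_computed(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        # second hand-worked list: q_i = min over j>=i of p_j * m / j
        assert bh_fdr([0.005, 0.04, 0.04, 0.8]) == pytest.approx(
            [0.02, 0.05333333, 0.05333333, 0.8])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_order_invariant_and_dominates_p(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        assert q_perm == pytest.approx(q[perm])


class TestGroupModels:
    def _cohort(self, rng, n=60, shift=0.0, or_=1.0):
        group = np.array(["HC"] * n + ["AN"] * n)
        age = rng.normal(16.3, 2.5, 2 * n)
        return group, age

    def test_binomial_null_or_near_one(self):
        rng = np.random.default_rng(7)
        group, age = self._cohort(rng, n=200)
        totals = np.full(400, 140)
        succ = rng.binomial(140, 0.4, size=400)
        res = binomial_group_model(succ, totals, group, age)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.08)

    def test_binomial_recovers_injected_odds_ratio(self):
        rng = np.random.default_rng(3)
        covered = 0
        for rep in range(40):
            group, age = self._cohort(rng, n=80)
            base = 0.35
            p_an = base * 1.5 / (1 - base + base * 1.5)  # OR = 1.5
            p = np.where(group == "AN", p_an, base)
            succ = rng.binomial(140, p)
            res = binomial_group_model(succ, np.full(160, 140), group, age)
            if res.ci_low <= np.log(1.5) <= res.ci_high:
                covered += 1
        assert covered >= 36  # 90% of replicates cover the true log-OR

    def test_binomial_separation_detected(self):
        group = np.array(["HC"] * 10 + ["AN"] * 10)
        succ = np.array([0] * 10 + [20] * 10)
        with pytest.raises(SeparationError):
            binomial_group_model(succ, np.full(20, 20), group, None)

    def test_gaussian_null_and_injected_shift(self):
        rng = np.random.default_rng(5)
        group, age = self._cohort(rng, n=80)
        y = rng.normal(0.6, 0.1, 160)
        res = gaussian_group_model(y, group, age)
        assert abs(res.estimate) < 0.05
        y2 = y + np.where(group == "AN", 0.5, 0.0)
        res2 = gaussian_group_model(y2, group, age)
        assert res2.ci_low <= 0.5 <= res2.ci_high

    def test_identical_groups_estimate_zero(self):
        group = np.array(["HC", "HC", "HC", "AN", "AN", "AN"])
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = gaussian_group_model(y, group, None)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_constant_age_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        group = np.array(["HC"] * 20 + ["AN"] * 20)
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="age covariate is constant"):
            gaussian_group_model(y, group, np.full(40, 16.0))


class TestCovariateAssociation:
    def test_constant_outcome_zero_slope(self):
        slope, t, p = covariate_association(np.ones(20), np.arange(20.0))
        assert slope == pytest.approx(0.0)

    def test_injected_negative_link_recovered(self):
        rng = np.random.default_rng(11)
        bmi = rng.normal(-3.2, 1.1, 80)
        prop_ss = 0.4 - 0.05 * (bmi + 3.2) + rng.normal(0, 0.05, 80)
        slope, t, p = covariate_association(prop_ss, bmi)
        assert slope < 0 and p < 0.05

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValidationError):
            covariate_association(np.arange(10.0), np.ones(10))


class TestMatchPairs:
    def test_identical_lists_zero_cost(self):
        ages = [14.0, 16.5, 19.2]
        res = match_pairs(ages, ages)
        assert res.total_abs_age_diff == 0.0
        assert res.max_abs_age_diff == 0.0

    def test_empty_cases(self):
        res = match_pairs([], [15.0, 16.0])
        assert res.pairs == () and res.total_abs_age_diff == 0.0

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValidationError):
            match_pairs([15.0, 16.0], [15.5])

    def test_matches_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            cases = rng.uniform(12, 26, size=4)
            pool = rng.uniform(12, 26, size=6)
            res = match_pairs(cases, pool)
            best = min(
                sum(abs(c - pool[j]) for c, j in zip(cases, perm))
                for perm in itertools.permutations(range(6), 4)
            )
            assert res.total_abs_age_diff == pytest.approx(best)

    def test_never_worse_than_greedy(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            cases = rng.uniform(12, 26, size=8)
            pool = list(rng.uniform(12, 26, size=12))
            greedy = 0.0
            avail = pool.copy()
            for c in cases:
                j = int(np.argmin([abs(c - a) for a in avail]))
                greedy += abs(c - avail.pop(j))
            assert match_pairs(cases, pool).total_abs_age_diff <= greedy + 1e-9
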
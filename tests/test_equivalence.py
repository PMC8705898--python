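"""Confidence-interval engines, acceptance ranges, and the bootstrap alternative."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topeq.equivalence import (
    ACCEPTANCE_RANGES,
    CIResult,
    GroupSummary,
    bootstrap_ci,
    ci_difference,
    ci_ratio,
    ci_ratio_log,
    range_check,
)


class TestCiDifference:
    def test_identical_groups_center_at_zero(self):
        g = GroupSummary(10.0, 1.0, 12)
        ci = ci_difference(g, g)
        assert ci.point == 0.0
        assert ci.lower == pytest.approx(-ci.upper)

    def test_half_width_closed_form(self):
        # equal arms (10, 1, 100): SE = sqrt(0.02), Welch df = 198
        g = GroupSummary(10.0, 1.0, 100)
        ci = ci_difference(g, g)
        assert ci.df == pytest.approx(198.0)
        expected = stats.t.ppf(0.95, 198) * math.sqrt(0.02)
        assert ci.upper == pytest.approx(expected, rel=1e-12)

    def test_pooled_df_rule(self):
        t, r = GroupSummary(12.0, 2.0, 8), GroupSummary(10.0, 3.0, 10)
        ci = ci_difference(t, r, df_rule="pooled")
        assert ci.df == 16.0
        sp2 = (7 * 4.0 + 9 * 9.0) / 16.0
        expected = stats.t.ppf(0.95, 16) * math.sqrt(sp2 * (1 / 8 + 1 / 10))
        assert ci.upper - ci.point == pytest.approx(expected)

    def test_parametric_bootstrap_oracle_agreement(self):
        """The t-interval matches a large parametric (normal) bootstrap of the
        difference of sample means within Monte-Carlo error."""
        t, r = GroupSummary(57.27, 4.08, 12), GroupSummary(56.69, 8.88, 12)
        ci = ci_difference(t, r)
        rng = np.random.default_rng(20210)
        reps = 200_000
        # simulate studentized differences to reproduce the t-interval's coverage
        xt = rng.normal(t.mean, t.sd, size=(reps, t.n))
        xr = rng.normal(r.mean, r.sd, size=(reps, r.n))
        diff = xt.mean(axis=1) - xr.mean(axis=1)
        lo, hi = np.quantile(diff, [0.05, 0.95])
        # normal-theory percentile interval is narrower than the t interval by
        # the t/z critical-value ratio and by SD estimation; allow a few percent
        se = math.sqrt(t.variance / t.n + r.variance / r.n)
        z = stats.norm.ppf(0.95)
        assert lo == pytest.approx(ci.point - z * se, abs=0.02 * se)
        assert hi == pytest.approx(ci.point + z * se, abs=0.02 * se)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 0.1, 1)


class TestCiRatio:
    def test_discrimination_table_reproduction(self):
        """Reduced-viscosity vs standard batch Q6h summaries give the printed
        interval 1.14-1.22 at two decimals."""
        ci = ci_ratio(GroupSummary(70.91, 2.92, 12), GroupSummary(60.13, 3.48, 12))
        assert round(ci.lower, 2) == 1.14
        assert round(ci.upper, 2) == 1.22

    def test_welch_and_pooled_agree_at_printed_precision(self):
        t, r = GroupSummary(70.91, 2.92, 12), GroupSummary(60.13, 3.48, 12)
        for rule in ("welch", "pooled"):
            ci = ci_ratio(t, r, df_rule=rule)
            assert (round(ci.lower, 2), round(ci.upper, 2)) == (1.14, 1.22)

    def test_equal_summaries_symmetric_around_one(self):
        g = GroupSummary(50.0, 5.0, 12)
        ci = ci_ratio(g, g)
        assert ci.point == 1.0
        assert ci.lower + ci.upper == pytest.approx(2.0)

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ci_ratio(GroupSummary(1.0, 0.1, 5), GroupSummary(0.0, 0.1, 5))

    @given(
        mt=st.floats(1.0, 100.0),
        mr=st.floats(1.0, 100.0),
        st_=st.floats(0.01, 20.0),
        sr=st.floats(0.01, 20.0),
        nt=st.integers(2, 40),
        nr=st.integers(2, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identity_with_difference_ci(self, mt, mr, st_, sr, nt, nr):
        """ci_ratio bounds equal the difference bounds shifted by the reference
        mean and divided by it — exact algebraic identity."""
        t, r = GroupSummary(mt, st_, nt), GroupSummary(mr, sr, nr)
        rci = ci_ratio(t, r)
        dci = ci_difference(t, r)
        assert rci.lower == pytest.approx((r.mean + dci.lower) / r.mean, rel=1e-12)
        assert rci.upper == pytest.approx((r.mean + dci.upper) / r.mean, rel=1e-12)
        assert rci.df == dci.df

    def test_width_decreases_in_n_and_increases_in_sd(self):
        base_t, base_r = GroupSummary(50.0, 5.0, 6), GroupSummary(48.0, 5.0, 6)
        w = ci_ratio(base_t, base_r).width
        widths_n = [
            ci_ratio(GroupSummary(50.0, 5.0, n), GroupSummary(48.0, 5.0, n)).width
            for n in (6, 12, 24, 48)
        ]
        assert all(a > b for a, b in zip(widths_n, widths_n[1:]))
        w_wide = ci_ratio(GroupSummary(50.0, 10.0, 6), base_r).width
        assert w_wide > w


class TestCiRatioLog:
    def test_equal_samples_point_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ci = ci_ratio_log(x, x)
        assert ci.point == pytest.approx(1.0)

    def test_scaling_reference_scales_interval(self):
        rng = np.random.default_rng(5)
        t = rng.lognormal(1.0, 0.3, 6)
        r = rng.lognormal(1.0, 0.3, 6)
        k = 3.7
        ci1 = ci_ratio_log(t, r)
        ci2 = ci_ratio_log(t, k * r)
        assert ci2.point == pytest.approx(ci1.point / k)
        assert ci2.lower == pytest.approx(ci1.lower / k)
        assert ci2.upper == pytest.approx(ci1.upper / k)

    def test_reciprocal_on_swapped_arms(self):
        rng = np.random.default_rng(6)
        t = rng.lognormal(0.0, 0.5, 6)
        r = rng.lognormal(0.2, 0.5, 6)
        fwd = ci_ratio_log(t, r)
        rev = ci_ratio_log(r, t)
        assert rev.lower == pytest.approx(1.0 / fwd.upper)
        assert rev.upper == pytest.approx(1.0 / fwd.lower)

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ci_ratio_log([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])

    def test_coverage_near_nominal_at_n6(self):
        """90% CI covers the true geometric-mean ratio ~90% of the time over
        lognormal donor means at n = 6 per arm."""
        rng = np.random.default_rng(777)
        n_sim, n = 2000, 6
        sigma = 0.5
        covered = 0
        for _ in range(n_sim):
            t = rng.lognormal(0.1, sigma, n)
            r = rng.lognormal(0.0, sigma, n)
            ci = ci_ratio_log(t, r)
            if ci.lower <= math.exp(0.1) <= ci.upper:
                covered += 1
        assert covered / n_sim == pytest.approx(0.90, abs=0.03)


class TestRangeCheck:
    @pytest.mark.parametrize(
        "bounds,range_name,status",
        [
            ((0.95, 1.05), "ivrt_90_111", "within"),
            ((0.5006, 0.9085), "ivpt_80_125", "straddles"),
            ((1.14, 1.22), "ivrt_90_111", "outside"),
            ((0.91, 1.12), "ivrt_90_111", "straddles"),
            ((1.26, 1.30), "ivpt_80_125", "outside"),
        ],
    )
    def test_classification(self, bounds, range_name, status):
        ci = CIResult(sum(bounds) / 2, bounds[0], bounds[1], df=10.0)
        assert range_check(ci, range_name).status == status

    def test_boundaries_count_as_within(self):
        for name, (lo, hi) in ACCEPTANCE_RANGES.items():
            ci = CIResult((lo + hi) / 2, lo, hi, df=10.0)
            assert range_check(ci, name).status == "within"

    @given(
        lower=st.floats(0.0, 2.0),
        width=st.floats(0.0, 1.0),
        name=st.sampled_from(sorted(ACCEPTANCE_RANGES)),
    )
    @settings(max_examples=300, deadline=None)
    def test_trichotomy(self, lower, width, name):
        ci = CIResult(lower + width / 2, lower, lower + width, df=5.0)
        verdict = range_check(ci, name)
        lo, hi = verdict.range
        statuses = {
            "within": lo <= ci.lower and ci.upper <= hi,
            "outside": ci.upper < lo or ci.lower > hi,
        }
        statuses["straddles"] = not statuses["within"] and not statuses["outside"]
        assert sum(statuses.values()) >= 1
        assert statuses[verdict.status]

    def test_unknown_range_rejected(self):
        ci = CIResult(1.0, 0.9, 1.1, df=5.0)
        with pytest.raises(ValueError, match="unknown acceptance range"):
            range_check(ci, "no_such_range")


class TestBootstrapCi:
    def test_constant_data_degenerate_interval(self):
        ci = bootstrap_ci([5.0] * 6, [2.0] * 6, reps=1000, seed=1)
        assert ci.lower == ci.point == ci.upper == 2.5

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        t, r = rng.normal(10, 1, 12), rng.normal(9, 1, 12)
        a = bootstrap_ci(t, r, reps=2000, seed=42)
        b = bootstrap_ci(t, r, reps=2000, seed=42)
        assert (a.lower, a.point, a.upper) == (b.lower, b.point, b.upper)

    def test_agrees_with_t_interval_for_large_normal_samples(self):
        rng = np.random.default_rng(11)
        t = rng.normal(100.0, 10.0, 200)
        r = rng.normal(95.0, 10.0, 200)
        boot = bootstrap_ci(t, r, reps=20_000, seed=7)
        para = ci_ratio(GroupSummary.from_values(t), GroupSummary.from_values(r))
        assert boot.lower == pytest.approx(para.lower, abs=0.005)
        assert boot.upper == pytest.approx(para.upper, abs=0.005)

    def test_requires_seed_and_enough_reps(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci([1.0, 2.0], [1.0, 2.0], reps=1000, seed=None)
        with pytest.raises(ValueError, match="reps"):
            bootstrap_ci([1.0, 2.0], [1.0, 2.0], reps=10, seed=1)
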
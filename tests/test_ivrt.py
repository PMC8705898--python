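"""Higuchi fitting and the IVRT method-validation suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topeq.equivalence import GroupSummary
from topeq.ivrt import (
    ReleaseParams,
    cv_percent,
    discriminatory_power,
    higuchi_fit,
    intermediate_precision,
    ivrt_equivalence,
    linearity_check,
    robustness_anova,
)

from conftest import make_profile

TIMES = np.array([0.5, 1, 2, 3, 4, 5, 6], dtype=float)


def _params(values, q6=None):
    return [
        ReleaseParams(f"r{i}", k=v, intercept=0.0, r2=1.0, q6=(q6[i] if q6 else v * 2))
        for i, v in enumerate(values)
    ]


class TestHiguchiFit:
    def test_exact_square_root_profile(self, higuchi_profile):
        p = higuchi_fit(higuchi_profile)
        assert p.k == pytest.approx(10.0)
        assert p.intercept == pytest.approx(0.0, abs=1e-10)
        assert p.r2 == pytest.approx(1.0)
        assert p.q6 == pytest.approx(10.0 * math.sqrt(6))

    def test_constant_profile_zero_slope(self):
        p = higuchi_fit(make_profile(TIMES, np.full(7, 42.0)))
        assert p.k == pytest.approx(0.0)
        assert p.q6 == pytest.approx(42.0)

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(99)
        true_k = 30.0
        q = np.maximum(true_k * np.sqrt(TIMES) + rng.normal(0, 1.0, TIMES.size), 0)
        p = higuchi_fit(make_profile(TIMES, q))
        res = stats.linregress(np.sqrt(TIMES), q)
        assert abs(p.k - true_k) < 3.0 * res.stderr

    @given(scale=st.floats(0.1, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_equivariance_under_q_scaling(self, scale):
        t = TIMES
        q = 7.0 * np.sqrt(t) + 1.5
        base = higuchi_fit(make_profile(t, q))
        scaled = higuchi_fit(make_profile(t, scale * q))
        assert scaled.k == pytest.approx(scale * base.k, rel=1e-9)
        assert scaled.intercept == pytest.approx(scale * base.intercept, rel=1e-6)
        assert scaled.q6 == pytest.approx(scale * base.q6, rel=1e-9)

    def test_forced_zero_intercept(self):
        q = 10.0 * np.sqrt(TIMES) + 5.0
        p = higuchi_fit(make_profile(TIMES, q), force_zero_intercept=True)
        assert p.intercept == 0.0
        assert p.k > 10.0  # the burst is absorbed into the slope

    def test_window_restricts_fit(self):
        # burst at 0.5 h then clean sqrt-t line
        q = 10.0 * np.sqrt(TIMES)
        q[0] += 20.0
        p_all = higuchi_fit(make_profile(TIMES, q))
        p_win = higuchi_fit(make_profile(TIMES, q), window=(1.0, 6.0))
        assert p_win.k == pytest.approx(10.0)
        assert abs(p_all.k - 10.0) > abs(p_win.k - 10.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            higuchi_fit(make_profile((1.0, 2.0), (1.0, 2.0)))

    def test_ci_coverage_of_true_k(self):
        """90% regression CI for K covers the generating K ~90% of the time."""
        rng = np.random.default_rng(2021)
        true_k, n_sim = 30.0, 500
        x = np.sqrt(TIMES)
        covered = 0
        for _ in range(n_sim):
            q = np.maximum(true_k * x + rng.normal(0, 1.5, x.size), 0)
            res = stats.linregress(x, q)
            half = stats.t.ppf(0.95, x.size - 2) * res.stderr
            if res.slope - half <= true_k <= res.slope + half:
                covered += 1
        assert covered / n_sim == pytest.approx(0.90, abs=0.03)


class TestLinearity:
    def test_proportional_k_gives_r2_one(self):
        by_strength = {s: _params([28.0 * s / 0.025] * 3) for s in (0.025, 0.05, 0.075)}
        res = linearity_check(by_strength)
        assert res.r2["k"] == pytest.approx(1.0)
        assert res.passed["k"] and res.passed["q6"]

    def test_flat_k_fails(self):
        by_strength = {s: _params([28.0, 28.5, 27.5]) for s in (0.025, 0.05, 0.075)}
        res = linearity_check(by_strength)
        assert res.r2["k"] < 0.5
        assert not res.passed["k"]

    def test_noisy_proportional_passes(self):
        rng = np.random.default_rng(4)
        by_strength = {
            s: _params(28.0 * s / 0.025 * (1 + rng.normal(0, 0.05, 12)))
            for s in (0.025, 0.05, 0.075)
        }
        res = linearity_check(by_strength)
        assert res.r2["k"] > 0.90
        assert res.passed["k"]

    def test_needs_three_strengths(self):
        with pytest.raises(ValueError, match="3 distinct strengths"):
            linearity_check({0.025: _params([1.0] * 3), 0.05: _params([2.0] * 3)})


class TestPrecision:
    def test_identical_values_zero_cv(self):
        res = intermediate_precision({"op1": _params([5.0] * 3), "op2": _params([5.0] * 3)})
        assert res.group_cv["op1"]["k"] == 0.0
        assert res.pooled_cv["k"] == 0.0
        assert res.passed["k"]

    def test_printed_operator_cv(self):
        """Mean 63.9 with SD 6.00 gives CV 9.39% at two decimals."""
        # construct 12 values with exactly that mean and SD
        base = np.array([-1.0] * 6 + [1.0] * 6)
        vals = 63.9 + 6.00 * base / base.std(ddof=1)
        assert round(cv_percent(vals), 2) == 9.39

    def test_pooled_cv_from_raw_replicates(self):
        groups = {"a": _params([10.0] * 3), "b": _params([20.0] * 3)}
        res = intermediate_precision(groups)
        six = np.array([10.0] * 3 + [20.0] * 3)
        assert res.pooled_cv["k"] == pytest.approx(100 * six.std(ddof=1) / 15.0)
        assert res.group_cv["a"]["k"] == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            intermediate_precision({"op1": _params([1.0, 2.0])})


class TestDiscrimination:
    def test_reduced_viscosity_batch_discriminates(self):
        res = discriminatory_power(
            GroupSummary(70.91, 2.92, 12), GroupSummary(60.13, 3.48, 12)
        )
        assert (round(res.ci.lower, 2), round(res.ci.upper, 2)) == (1.14, 1.22)
        assert res.discriminates

    def test_identical_summaries_do_not_discriminate(self):
        g = GroupSummary(60.0, 3.0, 12)
        res = discriminatory_power(g, g)
        assert res.ci.point == 1.0
        assert not res.discriminates

    def test_straddling_interval_has_no_discriminatory_power(self):
        # means ~11% apart with enough spread that the CI crosses 1.11
        res = discriminatory_power(GroupSummary(66.7, 8.0, 12), GroupSummary(60.0, 8.0, 12))
        assert res.verdict.status == "straddles"
        assert not res.discriminates


class TestRobustness:
    def test_identical_groups_f_zero(self):
        std = _params([10.0, 11.0, 12.0])
        out = robustness_anova(std, std)
        assert out["k"]["f"] == pytest.approx(0.0)
        assert out["k"]["p"] == pytest.approx(1.0)
        assert not out["k"]["significant"]

    def test_extreme_separation_significant(self):
        std = _params([10.0, 10.5, 11.0])
        mod = _params([20.0, 20.5, 21.0])  # offset ~20 SDs
        out = robustness_anova(std, mod)
        assert out["k"]["p"] < 0.001
        assert out["k"]["significant"]

    def test_type_i_error_rate_near_alpha(self):
        """Two groups from the same normal distribution reject at ~5%."""
        rng = np.random.default_rng(31)
        n_sim, rejections = 10_000, 0
        a = rng.normal(30, 3, size=(n_sim, 3))
        b = rng.normal(30, 3, size=(n_sim, 3))
        _, p = stats.f_oneway(a, b, axis=1)
        rejections = int(np.sum(p < 0.05))
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)

    def test_degenerate_variance_flagged_not_significant(self):
        std = _params([10.0, 10.0, 10.0])
        out = robustness_anova(std, std)
        assert math.isnan(out["k"]["p"])
        assert not out["k"]["significant"]


class TestIvrtEquivalence:
    def test_identical_arms_within_range(self):
        arm = _params([28.0, 29.0, 30.0, 27.5])
        rows = ivrt_equivalence(arm, arm)
        for row in rows.values():
            assert row.ratio == pytest.approx(1.0)
            assert row.verdict.status == "within"

    def test_ratio_matches_summary_ratio(self):
        rng = np.random.default_rng(8)
        test = _params(rng.normal(28.7, 2.2, 12))
        ref = _params(rng.normal(28.1, 5.4, 12))
        rows = ivrt_equivalence(test, ref)
        kt = np.mean([p.k for p in test])
        kr = np.mean([p.k for p in ref])
        assert rows["k"].ratio == pytest.approx(kt / kr)

    def test_shares_ci_engine_with_discrimination(self):
        """The equivalence table and the discriminatory-power check produce
        byte-identical CIResult objects for the same summaries."""
        rng = np.random.default_rng(9)
        test = _params(rng.normal(60, 3, 12))
        ref = _params(rng.normal(58, 3, 12))
        rows = ivrt_equivalence(test, ref)
        disc = discriminatory_power(
            GroupSummary.from_values([p.q6 for p in test]),
            GroupSummary.from_values([p.q6 for p in ref]),
        )
        assert rows["q6"].ci == disc.ci

    def test_needs_three_replicates(self):
        with pytest.raises(ValueError, match=">=3"):
            ivrt_equivalence(_params([1.0, 2.0]), _params([1.0, 2.0, 3.0]))
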
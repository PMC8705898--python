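"""In vitro release test (IVRT): Higuchi kinetics and method validation.

Release of a drug from a semisolid matrix through a synthetic membrane follows
square-root-of-time (Higuchi) kinetics over the usual 6 h experiment: the
cumulative amount per area Q(t) is linear in sqrt(t) with slope K, the release
constant. The method-validation suite covers the four checks a release method
must pass before batch comparison: linearity of K and Q6h across product
strengths, intermediate precision (CV% across operators/days), discriminatory
power against a deliberately altered formulation, and robustness to small
operational changes (one-way ANOVA per factor). Batch equivalence places a
90% ratio CI for K and Q6h inside the 90-111% release acceptance range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .equivalence import CIResult, EquivalenceVerdict, GroupSummary, ci_ratio, range_check
from .kinetics import CumulativeProfile, interpolate_q

__all__ = [
    "ReleaseParams",
    "LinearityResult",
    "PrecisionResult",
    "DiscriminationResult",
    "EquivalenceRow",
    "higuchi_fit",
    "linearity_check",
    "intermediate_precision",
    "discriminatory_power",
    "robustness_anova",
    "ivrt_equivalence",
    "cv_percent",
]

#: End-of-experiment time (h) at which the maximum released amount is read.
Q6H_TIME = 6.0


@dataclass(frozen=True)
class ReleaseParams:
    """Higuchi regression results for one replicate cell.

    K in µg·h^-1/2·cm^-2, intercept and q6 in µg/cm².
    """

    replicate_id: str
    k: float
    intercept: float
    r2: float
    q6: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.k):
            raise ValueError(f"replicate {self.replicate_id!r}: non-finite K")
        if np.isfinite(self.r2) and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"replicate {self.replicate_id!r}: r2={self.r2} outside [0, 1]")


def higuchi_fit(
    profile: CumulativeProfile,
    window: tuple[float, float] | None = None,
    force_zero_intercept: bool = False,
    q_end_time: float = Q6H_TIME,
) -> ReleaseParams:
    """Ordinary least squares of Q on sqrt(t).

    The default window is all strictly positive sampling times; an explicit
    ``window=(t_lo, t_hi)`` (closed) restricts the fit, e.g. to exclude an
    early burst. ``q6`` is the measured/interpolated amount at ``q_end_time``
    (NaN with a warning when that time is outside the sampled range), not the
    fitted line evaluated there.
    """
    t = np.asarray(profile.times_h)
    q = np.asarray(profile.q)
    mask = t > 0
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    t_fit, q_fit = t[mask], q[mask]
    if t_fit.size < 3:
        raise ValueError(
            f"replicate {profile.replicate_id!r}: need >=3 points in the fit window, "
            f"got {t_fit.size}"
        )
    x = np.sqrt(t_fit)
    if np.ptp(x) == 0:
        raise ValueError(f"replicate {profile.replicate_id!r}: zero variance in sqrt(t)")

    if force_zero_intercept:
        k = float(np.sum(q_fit * x) / np.sum(x * x))
        intercept = 0.0
        resid = q_fit - k * x
        ss_tot = float(np.sum((q_fit - q_fit.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        r2 = float(np.clip(r2, 0.0, 1.0))
    else:
        res = stats.linregress(x, q_fit)
        k, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)

    try:
        q6 = interpolate_q(profile, q_end_time)
    except ValueError:
        warnings.warn(
            f"replicate {profile.replicate_id!r}: {q_end_time} h outside sampled range; "
            "q6 reported as NaN",
            stacklevel=2,
        )
        q6 = float("nan")
    return ReleaseParams(profile.replicate_id, k, intercept, r2, q6)


def cv_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, 100·SD/mean (sample SD, n-1)."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class LinearityResult:
    """Per-parameter regression of individual replicate values on strength."""

    slope: dict[str, float]
    intercept: dict[str, float]
    r2: dict[str, float]
    passed: dict[str, bool]
    threshold: float


def linearity_check(
    params_by_strength: Mapping[float, Sequence[ReleaseParams]],
    r2_threshold: float = 0.90,
) -> LinearityResult:
    """Regress individual K and Q6h values on product strength (% w/w).

    The method is declared linear for a parameter when the regression r²
    exceeds ``r2_threshold`` (guideline value 0.90). Requires at least three
    distinct strengths.
    """
    if len(params_by_strength) < 3:
        raise ValueError(
            f"need >=3 distinct strengths, got {len(params_by_strength)}"
        )
    slope: dict[str, float] = {}
    intercept: dict[str, float] = {}
    r2: dict[str, float] = {}
    passed: dict[str, bool] = {}
    for name, getter in (("k", lambda p: p.k), ("q6", lambda p: p.q6)):
        xs, ys = [], []
        for strength, params in params_by_strength.items():
            for p in params:
                xs.append(float(strength))
                ys.append(getter(p))
        res = stats.linregress(xs, ys)
        slope[name] = float(res.slope)
        intercept[name] = float(res.intercept)
        r2[name] = float(res.rvalue**2)
        passed[name] = r2[name] > r2_threshold
    return LinearityResult(slope, intercept, r2, passed, r2_threshold)


@dataclass(frozen=True)
class PrecisionResult:
    """Intermediate-precision CVs per operator/day group and pooled."""

    group_cv: dict[str, dict[str, float]]  # group -> parameter -> CV%
    pooled_cv: dict[str, float]  # parameter -> CV% over all replicates
    passed: dict[str, bool]
    threshold: float


def intermediate_precision(
    groups: Mapping[str, Sequence[ReleaseParams]],
    cv_threshold: float = 10.0,
) -> PrecisionResult:
    """CV% of K and Q6h per group and pooled over all raw replicates.

    Pooled CVs are computed from the concatenated replicate values, not from
    group-level summaries. Pass when the pooled CV is below ``cv_threshold``
    (guideline value 10%).
    """
    if len(groups) < 2:
        raise ValueError("need at least two operator/day groups")
    group_cv: dict[str, dict[str, float]] = {}
    all_vals: dict[str, list[float]] = {"k": [], "q6": []}
    for gname, params in groups.items():
        ks = [p.k for p in params]
        q6s = [p.q6 for p in params]
        group_cv[gname] = {"k": cv_percent(ks), "q6": cv_percent(q6s)}
        all_vals["k"].extend(ks)
        all_vals["q6"].extend(q6s)
    pooled = {name: cv_percent(vals) for name, vals in all_vals.items()}
    passed = {name: val < cv_threshold for name, val in pooled.items()}
    return PrecisionResult(group_cv, pooled, passed, cv_threshold)


@dataclass(frozen=True)
class DiscriminationResult:
    ci: CIResult
    verdict: EquivalenceVerdict

    @property
    def discriminates(self) -> bool:
        """True when the whole CI lies outside the release acceptance range."""
        return self.verdict.status == "outside"


def discriminatory_power(
    test: GroupSummary,
    ref: GroupSummary,
    alpha: float = 0.10,
    df_rule: str = "welch",
) -> DiscriminationResult:
    """Negative-control check: the altered formulation's ratio CI must fall
    entirely outside the 90-111% range for the method to discriminate."""
    ci = ci_ratio(test, ref, alpha=alpha, df_rule=df_rule)  # type: ignore[arg-type]
    return DiscriminationResult(ci=ci, verdict=range_check(ci, "ivrt_90_111"))


def robustness_anova(
    standard: Sequence[ReleaseParams],
    modified: Sequence[ReleaseParams],
    alpha: float = 0.05,
) -> dict[str, dict[str, float | bool]]:
    """One-way ANOVA (two groups: standard vs modified condition) per parameter.

    Returns, per parameter, the F statistic, p-value and a ``significant``
    flag at ``alpha``. A degenerate layout (zero variance in both groups with
    equal means) yields NaN p with ``significant=False``.
    """
    if len(standard) < 2 or len(modified) < 2:
        raise ValueError("need >=2 replicates per condition")
    out: dict[str, dict[str, float | bool]] = {}
    for name, getter in (("k", lambda p: p.k), ("q6", lambda p: p.q6)):
        a = np.asarray([getter(p) for p in standard])
        b = np.asarray([getter(p) for p in modified])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(a, b)
        out[name] = {
            "f": float(f),
            "p": float(p),
            "significant": bool(np.isfinite(p) and p < alpha),
        }
    return out


@dataclass(frozen=True)
class EquivalenceRow:
    """One row of a release-equivalence table: a parameter compared between arms."""

    parameter: str
    n_test: int
    n_ref: int
    mean_test: float
    sd_test: float
    mean_ref: float
    sd_ref: float
    ratio: float
    ci: CIResult
    verdict: EquivalenceVerdict


def ivrt_equivalence(
    test: Sequence[ReleaseParams],
    ref: Sequence[ReleaseParams],
    alpha: float = 0.10,
    df_rule: str = "welch",
) -> dict[str, EquivalenceRow]:
    """Batch release equivalence for K and Q6h against the 90-111% range.

    Builds (mean, SD, n) summaries from replicate-level Higuchi parameters and
    applies the ratio CI; the same CI engine as :func:`discriminatory_power`.
    """
    if len(test) < 3 or len(ref) < 3:
        raise ValueError("need >=3 replicates per arm")
    rows: dict[str, EquivalenceRow] = {}
    for name, getter in (("k", lambda p: p.k), ("q6", lambda p: p.q6)):
        ts = GroupSummary.from_values([getter(p) for p in test])
        rs = GroupSummary.from_values([getter(p) for p in ref])
        ci = ci_ratio(ts, rs, alpha=alpha, df_rule=df_rule)  # type: ignore[arg-type]
        rows[name] = EquivalenceRow(
            parameter=name,
            n_test=ts.n,
            n_ref=rs.n,
            mean_test=ts.mean,
            sd_test=ts.sd,
            mean_ref=rs.mean,
            sd_ref=rs.sd,
            ratio=ci.point,
            ci=ci,
            verdict=range_check(ci, "ivrt_90_111"),
        )
    return rows
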
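"""Guideline equivalence statistics: 90% confidence intervals and acceptance ranges.

Regulatory equivalence of topical semisolids is assessed by placing a 90%
confidence interval for a test/reference comparison inside a named acceptance
range: 90-110% for quantitative physicochemical parameters, 90-111% for in
vitro release (IVRT) parameters, and the classical bioequivalence 80-125%
range for in vitro permeation (IVPT) parameters.

Two interval constructions are provided:

* an additive (difference-of-means) interval,
  ``(X̄t - X̄r) ± t * sqrt(s²t/nt + s²r/nr)``;
* a ratio interval obtained by shifting the difference interval by the
  reference mean and dividing by it, so the bounds live on the test/reference
  ratio scale used by the acceptance ranges.

For permeation endpoints a log-scale variant applies the difference interval
to log-transformed per-donor means and exponentiates, which yields an interval
for the ratio of geometric means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "CIResult",
    "EquivalenceVerdict",
    "ACCEPTANCE_RANGES",
    "ci_difference",
    "ci_ratio",
    "ci_ratio_log",
    "range_check",
    "bootstrap_ci",
]

#: Registered acceptance ranges (closed intervals on the ratio scale).
ACCEPTANCE_RANGES: dict[str, tuple[float, float]] = {
    "physchem_90_110": (0.90, 1.10),
    "ivrt_90_111": (0.90, 1.11),
    "ivpt_80_125": (0.80, 1.25),
}

DfRule = Literal["welch", "pooled"]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (mean, SD, n) for one arm of a comparison."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"need at least 2 observations, got n={self.n}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 observations")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class CIResult:
    """A two-sided confidence interval with its point estimate.

    ``kind`` records the scale: "difference" (analyte units) or "ratio"
    (dimensionless test/reference).
    """

    point: float
    lower: float
    upper: float
    df: float
    alpha: float = 0.10
    kind: str = "ratio"

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"inconsistent interval: lower={self.lower}, point={self.point}, upper={self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class EquivalenceVerdict:
    """Position of a ratio-scale CI relative to a named acceptance range."""

    range_name: str
    range: tuple[float, float]
    status: Literal["within", "outside", "straddles"]

    @property
    def equivalent(self) -> bool:
        return self.status == "within"


def _se_and_df(test: GroupSummary, ref: GroupSummary, df_rule: DfRule) -> tuple[float, float]:
    if df_rule == "welch":
        vt, vr = test.variance / test.n, ref.variance / ref.n
        se2 = vt + vr
        if se2 == 0.0:
            # Degenerate: both arms constant; any df gives a zero-width interval.
            return 0.0, float(test.n + ref.n - 2)
        df = se2**2 / (vt**2 / (test.n - 1) + vr**2 / (ref.n - 1))
        return math.sqrt(se2), df
    if df_rule == "pooled":
        df = test.n + ref.n - 2
        sp2 = ((test.n - 1) * test.variance + (ref.n - 1) * ref.variance) / df
        return math.sqrt(sp2 * (1.0 / test.n + 1.0 / ref.n)), float(df)
    raise ValueError(f"unknown df rule {df_rule!r}; expected 'welch' or 'pooled'")


def ci_difference(
    test: GroupSummary,
    ref: GroupSummary,
    alpha: float = 0.10,
    df_rule: DfRule = "welch",
) -> CIResult:
    """Two-sample CI for the difference of means, Welch-Satterthwaite df by default."""
    se, df = _se_and_df(test, ref, df_rule)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    point = test.mean - ref.mean
    half = tcrit * se
    return CIResult(point, point - half, point + half, df, alpha, kind="difference")


def ci_ratio(
    test: GroupSummary,
    ref: GroupSummary,
    alpha: float = 0.10,
    df_rule: DfRule = "welch",
) -> CIResult:
    """Ratio-scale CI: the difference interval shifted by the reference mean and
    divided by it, ``X̄t/X̄r ± t·SE/X̄r``.

    The standard-error term is scaled by the reference mean so the half-width is
    dimensionless, matching the ratio point estimate.
    """
    if ref.mean == 0:
        raise ValueError("reference mean is zero; ratio undefined")
    diff = ci_difference(test, ref, alpha=alpha, df_rule=df_rule)
    point = test.mean / ref.mean
    lower = (ref.mean + diff.lower) / ref.mean
    upper = (ref.mean + diff.upper) / ref.mean
    if lower > upper:  # negative reference mean flips the bounds
        lower, upper = upper, lower
    return CIResult(point, lower, upper, diff.df, alpha, kind="ratio")


def ci_ratio_log(
    test: Sequence[float],
    ref: Sequence[float],
    alpha: float = 0.10,
) -> CIResult:
    """CI for the ratio of geometric means via the difference interval on logs.

    The two-sample Welch interval is computed on log-transformed values and
    exponentiated; the point estimate is the geometric-mean ratio.
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(ref, dtype=float)
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValueError("log-scale CI requires strictly positive values")
    diff = ci_difference(
        GroupSummary.from_values(np.log(t)),
        GroupSummary.from_values(np.log(r)),
        alpha=alpha,
        df_rule="welch",
    )
    return CIResult(
        math.exp(diff.point),
        math.exp(diff.lower),
        math.exp(diff.upper),
        diff.df,
        alpha,
        kind="ratio",
    )


def range_check(ci: CIResult, range_name: str) -> EquivalenceVerdict:
    """Classify an interval against a named acceptance range.

    Ranges are closed: an interval touching a boundary still counts as within.
    Exactly one of {within, outside, straddles} holds for any interval.
    """
    try:
        lo, hi = ACCEPTANCE_RANGES[range_name]
    except KeyError:
        raise ValueError(
            f"unknown acceptance range {range_name!r}; registered: {sorted(ACCEPTANCE_RANGES)}"
        ) from None
    if lo <= ci.lower and ci.upper <= hi:
        status = "within"
    elif ci.upper < lo or ci.lower > hi:
        status = "outside"
    else:
        status = "straddles"
    return EquivalenceVerdict(range_name=range_name, range=(lo, hi), status=status)


def bootstrap_ci(
    test: Sequence[float],
    ref: Sequence[float],
    statistic: Literal["ratio_of_means", "ratio_of_geomeans"] = "ratio_of_means",
    reps: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.10,
) -> CIResult:
    """Nonparametric percentile bootstrap interval for a between-arm ratio.

    Resamples each arm independently with replacement ``reps`` times and takes
    the alpha/2 and 1-alpha/2 percentiles of the statistic. A resampling
    alternative to the t-based intervals when normality is doubtful.
    """
    if reps < 1000:
        raise ValueError("reps must be at least 1000 for a stable percentile interval")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    t = np.asarray(test, dtype=float)
    r = np.asarray(ref, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both arms must be non-empty")

    rng = np.random.default_rng(seed)
    ti = rng.integers(0, t.size, size=(reps, t.size))
    ri = rng.integers(0, r.size, size=(reps, r.size))
    if statistic == "ratio_of_means":
        stat = t[ti].mean(axis=1) / r[ri].mean(axis=1)
        point = float(t.mean() / r.mean())
    elif statistic == "ratio_of_geomeans":
        if np.any(t <= 0) or np.any(r <= 0):
            raise ValueError("geometric means require strictly positive values")
        stat = np.exp(np.log(t)[ti].mean(axis=1) - np.log(r)[ri].mean(axis=1))
        point = float(math.exp(np.log(t).mean() - np.log(r).mean()))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    lower, upper = np.quantile(stat, [alpha / 2.0, 1.0 - alpha / 2.0])
    # Guard against point falling outside the percentile band on degenerate data.
    lower = min(float(lower), point)
    upper = max(float(upper), point)
    return CIResult(point, lower, upper, df=float("nan"), alpha=alpha, kind="ratio")
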
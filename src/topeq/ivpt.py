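"""In vitro permeation test (IVPT): skin integrity, flux, donor-level equivalence.

Permeation through excised human skin is summarized by the steady-state
transdermal flux Jss (slope of the cumulative amount per area versus time over
the linear portion of the profile), the lag time (the t-axis intercept), and
the cumulative amount at the end of the 24 h experiment (Q24h). Skin pieces
are gated on transepithelial electrical resistance (TEER) before analysis.

Donor-to-donor variability dominates, so replicates within a donor are
collapsed to geometric means first and arm-level statistics operate on the
n-donor list. Equivalence uses the bioequivalence construction: a 90% CI on
the difference of log-transformed donor means, exponentiated to the ratio of
geometric means, judged against the 80-125% range. A mass balance (receptor +
skin + residual formulation over applied dose) closes the accounting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .equivalence import CIResult, EquivalenceVerdict, ci_ratio_log, range_check
from .kinetics import CumulativeProfile, interpolate_q

__all__ = [
    "DonorReplicate",
    "PermeationParams",
    "MassBalance",
    "MassBalanceSummary",
    "IvptEquivalenceResult",
    "teer_filter",
    "flux_fit",
    "donor_geomean",
    "ivpt_equivalence",
    "mass_balance",
    "mass_balance_cohort",
]

#: TEER cut-off (Ω) above which a skin piece is considered intact.
TEER_CUTOFF_OHM = 2000.0


@dataclass(frozen=True)
class DonorReplicate:
    """One Franz cell: a skin piece from a donor with its TEER and profile."""

    donor_id: str
    replicate_id: str
    teer_ohm: float
    profile: CumulativeProfile

    def __post_init__(self) -> None:
        if self.teer_ohm <= 0:
            raise ValueError(
                f"donor {self.donor_id!r} replicate {self.replicate_id!r}: TEER must be positive"
            )


@dataclass(frozen=True)
class PermeationParams:
    """Steady-state regression results for one cell.

    ``jss`` in the profile's mass unit per h per cm² (ng/h/cm² for HPLC-MS/MS
    data), ``lag`` in h (negative lags are reported, not suppressed), ``q24``
    in the profile's amount unit per cm² at the final sampling time.
    """

    replicate_id: str
    jss: float
    lag: float
    r2: float
    q24: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r2) and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"replicate {self.replicate_id!r}: r2 outside [0, 1]")


def teer_filter(
    replicates: Sequence[DonorReplicate],
    cutoff: float = TEER_CUTOFF_OHM,
) -> tuple[list[DonorReplicate], list[DonorReplicate]]:
    """Partition cells into (kept, excluded) by strict TEER > cutoff.

    Order is preserved in both lists; exclusions carry their ids for the log.
    """
    kept = [r for r in replicates if r.teer_ohm > cutoff]
    excluded = [r for r in replicates if r.teer_ohm <= cutoff]
    for r in excluded:
        warnings.warn(
            f"excluding donor {r.donor_id!r} replicate {r.replicate_id!r}: "
            f"TEER {r.teer_ohm:.0f} Ω <= {cutoff:.0f} Ω",
            stacklevel=2,
        )
    return kept, excluded


def _best_trailing_window(t: np.ndarray, q: np.ndarray, min_points: int = 5) -> np.ndarray:
    """Indices of the trailing window (ending at the last point) with the best
    linear fit: highest r², ties broken toward the longer window."""
    n = t.size
    if n <= min_points:
        return np.arange(n)
    best_start, best_r2 = 0, -np.inf
    for start in range(0, n - min_points + 1):
        res = stats.linregress(t[start:], q[start:])
        r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 0.0
        # strict > keeps the earliest (longest) window on ties
        if r2 > best_r2 + 1e-12:
            best_r2, best_start = r2, start
    return np.arange(best_start, n)


def flux_fit(
    profile: CumulativeProfile,
    window: tuple[float, float] | None = None,
) -> PermeationParams:
    """OLS of Q on t over the steady-state portion of a permeation profile.

    When no window is given, the steady-state region is taken as the trailing
    run of at least five points that maximizes the regression r² (the latest,
    most linear part of the profile). ``jss`` is the slope; ``lag`` is
    -intercept/slope when the slope is positive, otherwise undefined (NaN with
    a warning). ``q24`` is the cumulative amount at the final sampling time.
    """
    t = np.asarray(profile.times_h)
    q = np.asarray(profile.q)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t_fit, q_fit = t[mask], q[mask]
    else:
        idx = _best_trailing_window(t, q)
        t_fit, q_fit = t[idx], q[idx]
    if t_fit.size < 3:
        raise ValueError(
            f"replicate {profile.replicate_id!r}: need >=3 points in the fit window"
        )
    res = stats.linregress(t_fit, q_fit)
    jss = float(res.slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    if jss > 0:
        lag = float(-res.intercept / res.slope)
    else:
        warnings.warn(
            f"replicate {profile.replicate_id!r}: non-positive steady-state slope "
            f"({jss:.4g}); lag time undefined",
            stacklevel=2,
        )
        lag = float("nan")
    q24 = float(q[-1])
    return PermeationParams(profile.replicate_id, jss, lag, r2, q24)


def donor_geomean(
    params_by_donor: Mapping[str, Sequence[PermeationParams]],
) -> dict[str, dict[str, float]]:
    """Collapse within-donor replicates to geometric means of jss and q24.

    Donors with a non-positive value for a parameter are excluded for that
    parameter with a diagnostic warning (a geometric mean is undefined there).
    """
    out: dict[str, dict[str, float]] = {}
    for donor, params in params_by_donor.items():
        entry: dict[str, float] = {}
        for name, getter in (("jss", lambda p: p.jss), ("q24", lambda p: p.q24)):
            vals = np.asarray([getter(p) for p in params], dtype=float)
            if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
                warnings.warn(
                    f"donor {donor!r}: non-positive or non-finite {name}; "
                    "excluded from geometric-mean aggregation",
                    stacklevel=2,
                )
                continue
            entry[name] = float(np.exp(np.log(vals).mean()))
        if entry:
            out[donor] = entry
    return out


@dataclass(frozen=True)
class IvptEquivalenceResult:
    """Arm-level comparison of one permeation parameter on donor geometric means."""

    parameter: str
    n_test: int
    n_ref: int
    geomean_test: float
    geomean_ref: float
    ratio: float  # test/ref geometric-mean ratio
    ci: CIResult
    verdict: EquivalenceVerdict


def ivpt_equivalence(
    test_donor_means: Sequence[float],
    ref_donor_means: Sequence[float],
    parameter: str = "q24",
    alpha: float = 0.10,
) -> IvptEquivalenceResult:
    """Log-scale 90% CI for the test/reference geometric-mean ratio vs 80-125%.

    Inputs are the per-donor (replicate-collapsed) values of one parameter.
    """
    t = np.asarray(test_donor_means, dtype=float)
    r = np.asarray(ref_donor_means, dtype=float)
    if t.size < 3 or r.size < 3:
        raise ValueError("need >=3 donors per arm")
    ci = ci_ratio_log(t, r, alpha=alpha)
    gm_t = float(np.exp(np.log(t).mean()))
    gm_r = float(np.exp(np.log(r).mean()))
    return IvptEquivalenceResult(
        parameter=parameter,
        n_test=int(t.size),
        n_ref=int(r.size),
        geomean_test=gm_t,
        geomean_ref=gm_r,
        ratio=gm_t / gm_r,
        ci=ci,
        verdict=range_check(ci, "ivpt_80_125"),
    )


@dataclass(frozen=True)
class MassBalance:
    """Drug accounting for one cell, all amounts in µg."""

    receptor_ug: float
    skin_ug: float
    residual_ug: float
    applied_ug: float

    def __post_init__(self) -> None:
        for name in ("receptor_ug", "skin_ug", "residual_ug"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.applied_ug <= 0:
            raise ValueError("applied dose must be positive")

    @property
    def recovery_percent(self) -> float:
        return 100.0 * (self.receptor_ug + self.skin_ug + self.residual_ug) / self.applied_ug


@dataclass(frozen=True)
class MassBalanceSummary:
    recoveries: tuple[float, ...]
    mean: float
    min: float
    max: float
    flagged: tuple[int, ...]  # indices of cells outside the acceptance range
    range: tuple[float, float]


def mass_balance(
    receptor_ug: float, skin_ug: float, residual_ug: float, applied_ug: float
) -> MassBalance:
    """Per-cell mass balance; see :class:`MassBalance` for the recovery formula."""
    return MassBalance(receptor_ug, skin_ug, residual_ug, applied_ug)


def mass_balance_cohort(
    cells: Sequence[MassBalance],
    acceptance: tuple[float, float] = (90.0, 110.0),
) -> MassBalanceSummary:
    """Cohort recovery summary with per-cell flags outside ``acceptance`` (%).

    The guideline requirement applies to the cohort mean; individual cells
    outside the range are flagged but do not invalidate the study.
    """
    if not cells:
        raise ValueError("empty cohort")
    rec = tuple(c.recovery_percent for c in cells)
    lo, hi = acceptance
    flagged = tuple(i for i, r in enumerate(rec) if not (lo <= r <= hi))
    return MassBalanceSummary(
        recoveries=rec,
        mean=float(np.mean(rec)),
        min=float(np.min(rec)),
        max=float(np.max(rec)),
        flagged=flagged,
        range=acceptance,
    )
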
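"""Rheological descriptors for semisolid batch comparison.

Five descriptors summarize an emulsion's flow and viscoelastic behaviour:

* apparent viscosity at 300 s⁻¹ (η₃₀₀), read from the hold segment of a
  shear-rate loop or interpolated on the up ramp;
* relative thixotropic loop area (RTLA), the area enclosed between the up and
  down ramps of the stress-shear-rate loop as a percentage of the area under
  the up ramp: RTLA = 100 · S_thix / S_asc with S_thix = S_asc - S_desc;
* yield stress, the oscillatory stress amplitude at which the storage modulus
  G' falls a set fraction (default 10%) below its linear-viscoelastic (LVR)
  plateau;
* complex modulus G* = sqrt(G'² + G''²) and phase angle δ = atan(G''/G'),
  averaged over the LVR plateau.

Areas use trapezoidal integration over the sampled points only (no
extrapolation to the ends of the programmed ramp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equivalence import (
    CIResult,
    EquivalenceVerdict,
    GroupSummary,
    ci_ratio,
    range_check,
)

__all__ = [
    "FlowCurve",
    "OscSweep",
    "RheoParams",
    "NoPlateauError",
    "NoYieldError",
    "viscosity_at",
    "rtla",
    "yield_stress",
    "crossover_stress",
    "lvr_moduli",
    "rheo_equivalence",
]


class NoPlateauError(ValueError):
    """No linear-viscoelastic plateau could be detected in the sweep."""


class NoYieldError(ValueError):
    """G' never drops below the plateau threshold (no yield detected)."""


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("segment must be an (n, 2) array of (shear_rate, shear_stress)")
    return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class FlowCurve:
    """A shear-rate loop: up ramp, optional hold, down ramp.

    Each segment is a sequence of (shear_rate s⁻¹, shear_stress Pa) pairs; up
    rates non-decreasing, down rates non-increasing, rates within [0, 300].
    """

    up: tuple[tuple[float, float], ...]
    down: tuple[tuple[float, float], ...]
    hold: tuple[tuple[float, float], ...] = ()
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        up_r, _ = _as_xy(self.up)
        down_r, _ = _as_xy(self.down)
        if np.any(np.diff(up_r) < 0):
            raise ValueError("up-segment shear rates must be non-decreasing")
        if np.any(np.diff(down_r) > 0):
            raise ValueError("down-segment shear rates must be non-increasing")
        for r in (up_r, down_r):
            if np.any(r < 0) or np.any(r > 300.0 + 1e-9):
                raise ValueError("shear rates must lie within [0, 300] s^-1")


@dataclass(frozen=True)
class OscSweep:
    """Oscillatory stress sweep: (stress amplitude Pa, G' Pa, G'' Pa) triples."""

    points: tuple[tuple[float, float, float], ...]
    frequency_hz: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("points must be (stress, g_prime, g_double_prime) triples")
        s = arr[:, 0]
        if np.any(np.diff(s) <= 0):
            raise ValueError("stress amplitudes must be strictly increasing")
        if np.any(s < 0.1 - 1e-9) or np.any(s > 1000.0 + 1e-6):
            raise ValueError("stress amplitudes must lie within [0.1, 1000] Pa")
        if np.any(arr[:, 1:] <= 0):
            raise ValueError("moduli must be positive")

    @property
    def stress(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)[:, 0]

    @property
    def g_prime(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)[:, 1]

    @property
    def g_double_prime(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)[:, 2]


@dataclass(frozen=True)
class RheoParams:
    """The five batch-comparison descriptors for one rheometer run.

    Viscosity in Pa·s (flow-curve stress over rate has viscosity units even
    where instrument exports label the column in Pa), RTLA in %, yield stress
    and G* in Pa, δ in degrees.
    """

    eta300: float
    rtla: float
    yield_stress: float
    g_star: float
    delta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rtla):
            raise ValueError("RTLA must be finite")
        if not (0.0 <= self.delta <= 90.0):
            raise ValueError(f"phase angle {self.delta} outside [0, 90] degrees")


def viscosity_at(curve: FlowCurve, rate: float = 300.0) -> float:
    """Apparent viscosity σ/γ̇ (Pa·s) at ``rate``.

    Uses the hold-segment average when a hold at the requested rate exists,
    otherwise interpolates stress on the up ramp.
    """
    if rate <= 0:
        raise ValueError("shear rate must be positive")
    if curve.hold:
        hr, hs = _as_xy(curve.hold)
        if np.allclose(hr, rate, rtol=1e-3):
            return float(hs.mean() / rate)
    ur, us = _as_xy(curve.up)
    if not (ur[0] <= rate <= ur[-1]):
        raise ValueError(f"rate {rate} s^-1 outside the sampled up-ramp range")
    return float(np.interp(rate, ur, us) / rate)


def rtla(curve: FlowCurve) -> float:
    """Relative thixotropic loop area, %.

    S_asc is the trapezoidal area under the up ramp in stress-shear-rate
    coordinates, S_desc the area under the down ramp, and
    RTLA = 100 · (S_asc - S_desc) / S_asc. Zero for a fully reversible loop;
    negative values (anti-thixotropy) are reported as computed.
    """
    ur, us = _as_xy(curve.up)
    dr, ds = _as_xy(curve.down)
    if ur.size < 3 or dr.size < 3:
        raise ValueError("up and down segments each need >=3 points")
    s_asc = float(np.trapezoid(us, ur))
    s_desc = float(np.trapezoid(ds[::-1], dr[::-1]))
    if s_asc <= 0:
        raise ValueError("non-positive area under the up ramp")
    return 100.0 * (s_asc - s_desc) / s_asc


def _find_plateau(
    g_prime: np.ndarray,
    min_points: int = 4,
    spread: float = 0.05,
) -> slice:
    """First run of >= min_points consecutive points whose G' spread is below
    ``spread`` of their mean, extended while the condition holds."""
    n = g_prime.size
    for start in range(0, n - min_points + 1):
        end = start + min_points
        win = g_prime[start:end]
        if np.ptp(win) < spread * win.mean():
            while end < n:
                win = g_prime[start : end + 1]
                if np.ptp(win) < spread * win.mean():
                    end += 1
                else:
                    break
            return slice(start, end)
    raise NoPlateauError(
        f"no linear-viscoelastic plateau of {min_points} points within "
        f"{spread:.0%} spread detected"
    )


def yield_stress(sweep: OscSweep, deviation: float = 0.10) -> float:
    """Oscillatory yield stress: where G' drops ``deviation`` below the LVR plateau.

    The plateau mean is taken over the detected LVR window; the returned
    stress is the log-interpolated amplitude at which G' crosses
    (1 - deviation) · plateau mean. Raises :class:`NoYieldError` when G'
    never drops that far (e.g. a flat sweep).
    """
    if not (0.0 < deviation < 1.0):
        raise ValueError("deviation must be in (0, 1)")
    g = sweep.g_prime
    s = sweep.stress
    plateau = _find_plateau(g)
    threshold = (1.0 - deviation) * float(g[plateau].mean())
    below = np.nonzero(g < threshold)[0]
    below = below[below >= plateau.stop - 1]
    if below.size == 0:
        raise NoYieldError("no yield detected: G' never drops below the plateau threshold")
    j = int(below[0])
    if j == 0:
        return float(s[0])
    # log-interpolate the crossing between the bracketing points
    g_hi, g_lo = g[j - 1], g[j]
    frac = (g_hi - threshold) / (g_hi - g_lo)
    log_s = math.log10(s[j - 1]) + frac * (math.log10(s[j]) - math.log10(s[j - 1]))
    return float(10.0**log_s)


def crossover_stress(sweep: OscSweep) -> float:
    """Alternative yield metric: the amplitude where G' and G'' cross (G' = G'').

    Log-interpolated between the bracketing points; raises
    :class:`NoYieldError` when no crossover occurs in the sweep.
    """
    g1, g2, s = sweep.g_prime, sweep.g_double_prime, sweep.stress
    d = g1 - g2
    sign_change = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if sign_change.size == 0:
        raise NoYieldError("no G'/G'' crossover in the sweep")
    j = int(sign_change[0])
    frac = d[j] / (d[j] - d[j + 1])
    log_s = math.log10(s[j]) + frac * (math.log10(s[j + 1]) - math.log10(s[j]))
    return float(10.0**log_s)


def lvr_moduli(sweep: OscSweep) -> tuple[float, float]:
    """(G*, δ) averaged over the linear-viscoelastic plateau.

    G* = sqrt(G'² + G''²) in Pa; δ = atan(G''/G') in degrees.
    """
    plateau = _find_plateau(sweep.g_prime)
    g1 = sweep.g_prime[plateau]
    g2 = sweep.g_double_prime[plateau]
    g_star = float(np.mean(np.hypot(g1, g2)))
    delta = float(np.mean(np.degrees(np.arctan2(g2, g1))))
    return g_star, delta


def rheo_equivalence(
    test: Sequence[RheoParams],
    ref: Sequence[RheoParams],
    alpha: float = 0.10,
) -> dict[str, dict[str, object]]:
    """Per-descriptor ratio CIs against the physicochemical 90-110% range.

    Returns a mapping descriptor -> {summary stats, ci: CIResult,
    verdict: EquivalenceVerdict}.
    """
    if len(test) < 2 or len(ref) < 2:
        raise ValueError("need >=2 replicates per arm")
    out: dict[str, dict[str, object]] = {}
    for name in ("eta300", "rtla", "yield_stress", "g_star", "delta"):
        ts = GroupSummary.from_values([getattr(p, name) for p in test])
        rs = GroupSummary.from_values([getattr(p, name) for p in ref])
        ci: CIResult = ci_ratio(ts, rs, alpha=alpha)
        verdict: EquivalenceVerdict = range_check(ci, "physchem_90_110")
        out[name] = {
            "mean_test": ts.mean,
            "sd_test": ts.sd,
            "mean_ref": rs.mean,
            "sd_ref": rs.sd,
            "ratio": ci.point,
            "ci": ci,
            "verdict": verdict,
        }
    return out
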
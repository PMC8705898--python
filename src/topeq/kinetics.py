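"""Franz diffusion-cell kinetics: sampling records to cumulative release profiles.

A vertical (Franz) diffusion cell holds the formulation in a donor compartment
above a membrane or skin section; drug diffuses into a stirred receptor
compartment that is sampled periodically, each aliquot being replaced with
fresh medium. Because each draw removes drug, the cumulative amount released
through the membrane at draw ``n`` must add back what earlier draws removed:

    Q_n = (C_n * V_receptor + sum_{i<n} C_i * V_sample) / A

with concentrations ``C`` in mass/mL, volumes in mL and the diffusion area
``A`` in cm², giving ``Q`` in mass/cm². Both the release (IVRT) and the
permeation (IVPT) analyses start from these corrected profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellConfig",
    "SamplingRecord",
    "CumulativeProfile",
    "cumulative_profile",
    "interpolate_q",
]

#: Mass-concentration units accepted for sampling records, mapped to the mass
#: unit of the resulting cumulative profile (per cm²).
_UNIT_TO_Q_UNIT = {"ug/mL": "ug/cm2", "ng/mL": "ng/cm2"}


@dataclass(frozen=True)
class CellConfig:
    """Geometry and dosing of one diffusion cell."""

    receptor_volume_ml: float
    sample_volume_ml: float
    diffusion_area_cm2: float
    applied_dose_mg: float | None = None
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        for name in ("receptor_volume_ml", "sample_volume_ml", "diffusion_area_cm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_volume_ml >= self.receptor_volume_ml:
            raise ValueError("sample_volume_ml must be smaller than receptor_volume_ml")
        if self.applied_dose_mg is not None and self.applied_dose_mg <= 0:
            raise ValueError("applied_dose_mg must be positive when given")


@dataclass(frozen=True)
class SamplingRecord:
    """Raw receptor concentrations for one replicate cell.

    ``unit`` declares the concentration unit of the file the record came from
    ("ug/mL" for IVRT-style HPLC data, "ng/mL" for IVPT-style HPLC-MS/MS data).
    """

    replicate_id: str
    times_h: tuple[float, ...]
    concentrations: tuple[float, ...]
    unit: str = "ug/mL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", tuple(float(t) for t in self.times_h))
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if len(self.times_h) != len(self.concentrations):
            raise ValueError(
                f"replicate {self.replicate_id!r}: {len(self.times_h)} times but "
                f"{len(self.concentrations)} concentrations"
            )
        t = np.asarray(self.times_h)
        if t.size == 0:
            raise ValueError(f"replicate {self.replicate_id!r}: empty record")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"replicate {self.replicate_id!r}: times must be non-negative and strictly increasing"
            )
        if any(c < 0 for c in self.concentrations):
            raise ValueError(
                f"replicate {self.replicate_id!r}: negative concentration encountered"
            )
        if self.unit not in _UNIT_TO_Q_UNIT:
            raise ValueError(
                f"replicate {self.replicate_id!r}: unknown unit {self.unit!r}; "
                f"expected one of {sorted(_UNIT_TO_Q_UNIT)}"
            )


@dataclass(frozen=True)
class CumulativeProfile:
    """Sampling-corrected cumulative amount per unit area versus time.

    ``q`` is not forced to be non-decreasing: analytical noise can produce
    small local decreases and these are kept as measured.
    """

    replicate_id: str
    times_h: tuple[float, ...]
    q: tuple[float, ...]
    q_unit: str = "ug/cm2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", tuple(float(t) for t in self.times_h))
        object.__setattr__(self, "q", tuple(float(v) for v in self.q))
        if len(self.times_h) != len(self.q):
            raise ValueError(f"replicate {self.replicate_id!r}: times/q length mismatch")
        if any(v < 0 for v in self.q):
            raise ValueError(f"replicate {self.replicate_id!r}: negative cumulative amount")


def cumulative_profile(
    record: SamplingRecord,
    cell: CellConfig,
    correct_sampling: bool = True,
) -> CumulativeProfile:
    """Apply the sampling-replacement mass balance to one replicate.

    With ``correct_sampling=False`` the previously-withdrawn-mass term is
    dropped (Q_n = C_n * V_receptor / A), for data already corrected upstream.
    """
    c = np.asarray(record.concentrations, dtype=float)
    vr = cell.receptor_volume_ml
    vs = cell.sample_volume_ml
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]]) if correct_sampling else 0.0
    q = (c * vr + prior * vs) / cell.diffusion_area_cm2
    return CumulativeProfile(
        replicate_id=record.replicate_id,
        times_h=record.times_h,
        q=tuple(q),
        q_unit=_UNIT_TO_Q_UNIT[record.unit],
    )


def interpolate_q(profile: CumulativeProfile, t: float) -> float:
    """Cumulative amount at time ``t`` (h): exact at sampled points, linear between.

    Extrapolation outside the sampled time range is refused.
    """
    times = np.asarray(profile.times_h)
    if not (times[0] <= t <= times[-1]):
        raise ValueError(
            f"replicate {profile.replicate_id!r}: t={t} h outside sampled range "
            f"[{times[0]}, {times[-1]}] h; extrapolation not supported"
        )
    return float(np.interp(t, times, np.asarray(profile.q)))
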
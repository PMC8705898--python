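"""CSV and config I/O for the analysis pipeline.

Dialects
--------
sampling CSV (IVRT)    : replicate_id, time_h, concentration, unit
sampling CSV (IVPT)    : donor_id, replicate_id, teer_ohm, time_h, concentration, unit
cumulative-profile CSV : replicate_id, time_h, q, q_unit
flow-curve CSV         : segment (up|hold|down), shear_rate_1_per_s, shear_stress_pa
oscillation CSV        : stress_pa, g_prime_pa, g_double_prime_pa
droplet CSV            : batch_id, diameter_um
diffractogram CSV      : two_theta_deg, intensity

Cell geometry and analysis options travel in a YAML/JSON config block rather
than in the data files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .ivpt import DonorReplicate
from .kinetics import CellConfig, CumulativeProfile, SamplingRecord, cumulative_profile
from .microstructure import Diffractogram, DropletSample
from .rheology import FlowCurve, OscSweep

__all__ = [
    "read_sampling_csv",
    "read_ivpt_csv",
    "write_sampling_csv",
    "write_ivpt_csv",
    "write_profiles_csv",
    "read_flow_csv",
    "write_flow_csv",
    "read_osc_csv",
    "write_osc_csv",
    "read_droplets_csv",
    "write_droplets_csv",
    "read_diffractogram_csv",
    "write_diffractogram_csv",
    "load_config",
    "cell_from_config",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty input file")
    return df


def read_sampling_csv(path) -> list[SamplingRecord]:
    """Long-format receptor sampling records, one row per draw."""
    df = _read_csv(path)
    _require_columns(df, ("replicate_id", "time_h", "concentration"), path)
    unit_col = df["unit"] if "unit" in df.columns else None
    records = []
    for rid, grp in df.groupby("replicate_id", sort=False):
        grp = grp.sort_values("time_h")
        unit = str(grp["unit"].iloc[0]) if unit_col is not None else "ug/mL"
        records.append(
            SamplingRecord(
                replicate_id=str(rid),
                times_h=tuple(grp["time_h"]),
                concentrations=tuple(grp["concentration"]),
                unit=unit,
            )
        )
    return records


def write_sampling_csv(records: Sequence[SamplingRecord], path) -> None:
    rows = [
        {"replicate_id": r.replicate_id, "time_h": t, "concentration": c, "unit": r.unit}
        for r in records
        for t, c in zip(r.times_h, r.concentrations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ivpt_csv(path, cell: CellConfig) -> list[DonorReplicate]:
    """IVPT sampling CSV with donor and TEER metadata; profiles are corrected here."""
    df = _read_csv(path)
    _require_columns(
        df, ("donor_id", "replicate_id", "teer_ohm", "time_h", "concentration"), path
    )
    out = []
    for (donor, rid), grp in df.groupby(["donor_id", "replicate_id"], sort=False):
        grp = grp.sort_values("time_h")
        unit = str(grp["unit"].iloc[0]) if "unit" in grp.columns else "ng/mL"
        record = SamplingRecord(
            replicate_id=str(rid),
            times_h=tuple(grp["time_h"]),
            concentrations=tuple(grp["concentration"]),
            unit=unit,
        )
        out.append(
            DonorReplicate(
                donor_id=str(donor),
                replicate_id=str(rid),
                teer_ohm=float(grp["teer_ohm"].iloc[0]),
                profile=cumulative_profile(record, cell),
            )
        )
    return out


def write_ivpt_csv(replicates: Sequence[DonorReplicate], records: Sequence[SamplingRecord], path) -> None:
    """Write donor replicates alongside their raw sampling records.

    ``records`` must be parallel to ``replicates`` (same order); the raw
    concentrations are what an instrument would export, so that is what the
    file carries.
    """
    rows = []
    for rep, rec in zip(replicates, records):
        for t, c in zip(rec.times_h, rec.concentrations):
            rows.append(
                {
                    "donor_id": rep.donor_id,
                    "replicate_id": rep.replicate_id,
                    "teer_ohm": rep.teer_ohm,
                    "time_h": t,
                    "concentration": c,
                    "unit": rec.unit,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_profiles_csv(profiles: Sequence[CumulativeProfile], path) -> None:
    rows = [
        {"replicate_id": p.replicate_id, "time_h": t, "q": q, "q_unit": p.q_unit}
        for p in profiles
        for t, q in zip(p.times_h, p.q)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flow_csv(path) -> FlowCurve:
    df = _read_csv(path)
    _require_columns(df, ("segment", "shear_rate_1_per_s", "shear_stress_pa"), path)
    seg = {
        name: tuple(zip(grp["shear_rate_1_per_s"], grp["shear_stress_pa"]))
        for name, grp in df.groupby("segment", sort=False)
    }
    unknown = set(seg) - {"up", "hold", "down"}
    if unknown:
        raise ValueError(f"{path}: unknown flow-curve segment(s) {sorted(unknown)}")
    if "up" not in seg or "down" not in seg:
        raise ValueError(f"{path}: flow curve needs both 'up' and 'down' segments")
    return FlowCurve(up=seg["up"], down=seg["down"], hold=seg.get("hold", ()))


def write_flow_csv(curve: FlowCurve, path) -> None:
    rows = []
    for name in ("up", "hold", "down"):
        for rate, stress in getattr(curve, name):
            rows.append(
                {"segment": name, "shear_rate_1_per_s": rate, "shear_stress_pa": stress}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_osc_csv(path) -> OscSweep:
    df = _read_csv(path)
    _require_columns(df, ("stress_pa", "g_prime_pa", "g_double_prime_pa"), path)
    df = df.sort_values("stress_pa")
    return OscSweep(
        points=tuple(zip(df["stress_pa"], df["g_prime_pa"], df["g_double_prime_pa"]))
    )


def write_osc_csv(sweep: OscSweep, path) -> None:
    pd.DataFrame(
        sweep.points, columns=["stress_pa", "g_prime_pa", "g_double_prime_pa"]
    ).to_csv(path, index=False)


def read_droplets_csv(path) -> dict[str, DropletSample]:
    df = _read_csv(path)
    _require_columns(df, ("batch_id", "diameter_um"), path)
    return {
        str(batch): DropletSample(batch_id=str(batch), diameters_um=tuple(grp["diameter_um"]))
        for batch, grp in df.groupby("batch_id", sort=False)
    }


def write_droplets_csv(samples: Sequence[DropletSample], path) -> None:
    rows = [
        {"batch_id": s.batch_id, "diameter_um": d}
        for s in samples
        for d in s.diameters_um
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_diffractogram_csv(path) -> Diffractogram:
    df = _read_csv(path)
    _require_columns(df, ("two_theta_deg", "intensity"), path)
    df = df.sort_values("two_theta_deg")
    return Diffractogram(
        two_theta_deg=tuple(df["two_theta_deg"]), intensity=tuple(df["intensity"])
    )


def write_diffractogram_csv(d: Diffractogram, path) -> None:
    pd.DataFrame(
        {"two_theta_deg": d.two_theta_deg, "intensity": d.intensity}
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def cell_from_config(cfg: dict) -> CellConfig:
    """Build a :class:`CellConfig` from a config block (keys as field names)."""
    cell = cfg.get("cell", cfg)
    try:
        return CellConfig(
            receptor_volume_ml=float(cell["receptor_volume_ml"]),
            sample_volume_ml=float(cell["sample_volume_ml"]),
            diffusion_area_cm2=float(cell["diffusion_area_cm2"]),
            applied_dose_mg=(
                float(cell["applied_dose_mg"]) if "applied_dose_mg" in cell else None
            ),
            temperature_c=(
                float(cell["temperature_c"]) if "temperature_c" in cell else None
            ),
        )
    except KeyError as exc:
        raise ValueError(f"cell config missing required key {exc}") from None
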
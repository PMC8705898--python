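"""Synthetic study generators for every input class the pipeline consumes.

Laboratory data for this kind of study are rarely deposited, so each stage is
exercised with generators that reproduce the statistical structure the
analysis assumes:

* IVRT release: square-root-of-time kinetics with multiplicative
  replicate-to-replicate variation of the release constant and additive
  measurement noise on cumulative amounts, emitted as raw *concentration*
  records (inverted through the Franz sampling correction) so the correction
  code path is always exercised;
* IVPT permeation: steady-state flux with a lag time and a lognormal
  donor -> replicate variance hierarchy (donor variability dominating, as seen
  in skin studies), plus TEER draws with a configurable failing fraction;
* flow curves: a Herschel-Bulkley up ramp, a hold at the top rate, and a down
  ramp scaled to hit a target relative thixotropic loop area exactly;
* oscillatory sweeps: a G' plateau with power-law decay past a critical
  stress, constant phase angle;
* droplet diameters: lognormal samples moment-matched to a target mean/SD;
* diffractograms: Gaussian reflections on a wide amorphous hump with
  counting-like noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetics import CellConfig, SamplingRecord
from .microstructure import Diffractogram, DropletSample, PeakSet
from .rheology import FlowCurve, OscSweep
from .ivpt import DonorReplicate
from .kinetics import cumulative_profile

__all__ = [
    "Arm",
    "StudyScenario",
    "IVRT_TIMES_H",
    "IVPT_TIMES_H",
    "IVRT_CELL",
    "IVPT_CELL",
    "default_scenario",
    "gen_release",
    "gen_permeation",
    "gen_flow_curve",
    "gen_osc_sweep",
    "gen_droplets",
    "gen_diffractogram",
    "lognormal_params",
]

#: IVRT sampling schedule (h): sub-6 h draws from a 6 h experiment.
IVRT_TIMES_H: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
#: IVPT sampling schedule (h) up to 24 h (t = 0 carried as a zero sample).
IVPT_TIMES_H: tuple[float, ...] = (
    0.0, 1.5, 2.5, 3.5, 5.5, 7.5, 9.5, 11.5, 14.5, 17.5, 20.5, 24.0,
)

#: Release-cell geometry: ~12 mL receptor, 1.54 cm² area, 300 µL draws.
IVRT_CELL = CellConfig(
    receptor_volume_ml=12.0,
    sample_volume_ml=0.3,
    diffusion_area_cm2=1.54,
    temperature_c=37.0,
)
#: Permeation-cell geometry: 1 cm² diffusion surface; 7 mL receptor and 300 µL
#: draws are typical for skin-mounted vertical cells.
IVPT_CELL = CellConfig(
    receptor_volume_ml=7.0,
    sample_volume_ml=0.3,
    diffusion_area_cm2=1.0,
    temperature_c=32.0,
)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _cv_sigma(cv: float) -> float:
    """Lognormal log-SD giving a multiplicative factor with unit mean and CV ``cv``."""
    return math.sqrt(math.log(1.0 + cv**2))


def _unit_mean_lognormal(rng: np.random.Generator, cv: float) -> float:
    """One multiplicative lognormal factor with unit mean and the given CV."""
    if cv == 0:
        return 1.0
    sigma = _cv_sigma(cv)
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


@dataclass(frozen=True)
class Arm:
    """One study arm (a batch or control) and its generating truth.

    ``true_k`` in µg·h^-1/2·cm^-2 (a 0.025% emulsion releases at roughly
    28 µg·h^-1/2·cm^-2 and K scales with strength); ``true_jss`` in
    ng·h^-1·cm^-2 with ``true_lag`` in h; ``donor_cv``/``replicate_cv`` are
    multiplicative lognormal coefficients of variation; ``noise_sd`` is the
    additive noise SD on IVRT cumulative amounts (µg/cm²).
    """

    label: str
    strength_pct: float = 0.025
    true_k: float = 28.0
    true_jss: float = 15.0
    true_lag: float = 2.0
    donor_cv: float = 0.55
    replicate_cv: float = 0.08
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.strength_pct <= 0:
            raise ValueError("strength must be positive")
        for name in ("donor_cv", "replicate_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StudyScenario:
    """A full study design: arms plus sampling schedules and a mandatory seed."""

    arms: tuple[Arm, ...]
    ivrt_times_h: tuple[float, ...] = IVRT_TIMES_H
    ivpt_times_h: tuple[float, ...] = IVPT_TIMES_H
    seed: int = 0

    def arm(self, label: str) -> Arm:
        for a in self.arms:
            if a.label == label:
                return a
        raise KeyError(f"no arm labelled {label!r}")


def default_scenario(seed: int) -> StudyScenario:
    """The pilot design: three 0.025% batches (12 IVRT replicates each) and,
    for permeation, two batches plus a double-strength negative control with
    six donors and two replicates per donor."""
    return StudyScenario(
        arms=(
            Arm("batch1", true_k=28.7, true_jss=15.1),
            Arm("batch2", true_k=28.1),
            Arm("batch3", true_k=28.0, true_jss=13.6),
            Arm("negative_control", strength_pct=0.05, true_k=56.0, true_jss=22.6),
        ),
        seed=seed,
    )


def gen_release(
    arm: Arm,
    n_replicates: int,
    seed: int,
    times_h: Sequence[float] = IVRT_TIMES_H,
    cell: CellConfig = IVRT_CELL,
) -> list[SamplingRecord]:
    """Simulate IVRT concentration records for one arm.

    Per replicate, K is drawn lognormally around ``arm.true_k`` with CV
    ``arm.replicate_cv``; cumulative amounts K·sqrt(t) + N(0, noise_sd) are
    inverted through the sampling-replacement correction to the receptor
    concentrations a chromatograph would report (clipped at zero).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray([x for x in times_h if x > 0], dtype=float)
    records = []
    for i in range(n_replicates):
        k = arm.true_k * _unit_mean_lognormal(rng, arm.replicate_cv)
        q = k * np.sqrt(t) + rng.normal(0.0, arm.noise_sd, size=t.size)
        q = np.maximum(q, 0.0)
        records.append(
            _invert_correction(f"{arm.label}-r{i + 1:02d}", t, q, cell, unit="ug/mL")
        )
    return records


def _invert_correction(
    replicate_id: str,
    times_h: np.ndarray,
    q: np.ndarray,
    cell: CellConfig,
    unit: str,
) -> SamplingRecord:
    """Solve the sampling-correction recurrence for concentrations given Q."""
    conc = np.zeros_like(q)
    running = 0.0  # sum of previous concentrations
    for n in range(q.size):
        c = (q[n] * cell.diffusion_area_cm2 - running * cell.sample_volume_ml) / (
            cell.receptor_volume_ml
        )
        c = max(c, 0.0)
        conc[n] = c
        running += c
    return SamplingRecord(replicate_id, tuple(times_h), tuple(conc), unit=unit)


def gen_permeation(
    arm: Arm,
    n_donors: int = 6,
    reps_per_donor: int = 2,
    seed: int = 0,
    times_h: Sequence[float] = IVPT_TIMES_H,
    cell: CellConfig = IVPT_CELL,
    noise_cv: float = 0.05,
    teer_fail_fraction: float = 0.0,
) -> list[DonorReplicate]:
    """Simulate IVPT donor replicates for one arm.

    Flux for donor d, replicate r is ``true_jss · D_d · R_r`` with lognormal
    donor and replicate factors (unit mean, CVs from the arm); the cumulative
    profile is ``jss · max(t - lag, 0)`` (ng/cm²) with multiplicative
    measurement noise of CV ``noise_cv``, re-emitted as ng/mL concentration
    records. TEER values are drawn above the 2000 Ω cut-off for passing cells
    and below it for a ``teer_fail_fraction`` of cells.
    """
    rng = np.random.default_rng(seed)
    t_all = np.asarray(times_h, dtype=float)
    out: list[DonorReplicate] = []
    for d in range(n_donors):
        donor_factor = _unit_mean_lognormal(rng, arm.donor_cv)
        for r in range(reps_per_donor):
            rep_factor = _unit_mean_lognormal(rng, arm.replicate_cv)
            jss = arm.true_jss * donor_factor * rep_factor
            q = jss * np.clip(t_all - arm.true_lag, 0.0, None)
            if noise_cv > 0:
                q = q * (1.0 + rng.normal(0.0, noise_cv, size=q.size))
            q = np.maximum(q, 0.0)
            if rng.random() < teer_fail_fraction:
                teer = rng.uniform(500.0, 1900.0)
            else:
                teer = rng.uniform(2500.0, 6000.0)
            donor_id = f"{arm.label}-d{d + 1:02d}"
            rep_id = f"{donor_id}-r{r + 1}"
            record = _invert_correction(rep_id, t_all, q, cell, unit="ng/mL")
            out.append(
                DonorReplicate(
                    donor_id=donor_id,
                    replicate_id=rep_id,
                    teer_ohm=float(teer),
                    profile=cumulative_profile(record, cell),
                )
            )
    return out


def gen_flow_curve(
    yield_stress_pa: float = 20.0,
    consistency: float = 4.97,
    flow_index: float = 0.5,
    thixo_fraction: float = 0.526,
    n_points: int = 200,
    seed: int | None = None,
    noise_cv: float = 0.0,
    max_rate: float = 300.0,
) -> FlowCurve:
    """A thixotropic shear-rate loop with a known relative loop area.

    The up ramp follows a Herschel-Bulkley law σ = σ_y + k·γ̇^n; the hold
    segment sits at the top rate; the down ramp is the up ramp scaled by
    (1 - thixo_fraction), so the relative thixotropic loop area is exactly
    ``100 · thixo_fraction`` in the noise-free case.
    """
    if not (0 <= thixo_fraction < 1):
        raise ValueError("thixo_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rate = np.linspace(0.0, max_rate, n_points)
    stress_up = yield_stress_pa + consistency * rate**flow_index
    stress_down = (1.0 - thixo_fraction) * stress_up
    if noise_cv > 0:
        stress_up = stress_up * (1.0 + rng.normal(0.0, noise_cv, n_points))
        stress_down = stress_down * (1.0 + rng.normal(0.0, noise_cv, n_points))
    hold_stress = stress_up[-1] * (
        1.0 + (rng.normal(0.0, noise_cv, 10) if noise_cv > 0 else np.zeros(10))
    )
    return FlowCurve(
        up=tuple(zip(rate, stress_up)),
        down=tuple(zip(rate[::-1], stress_down[::-1])),
        hold=tuple((max_rate, s) for s in hold_stress),
    )


def gen_osc_sweep(
    g_prime_plateau: float = 1300.0,
    delta_deg: float = 25.0,
    critical_stress: float = 74.2,
    decay_exponent: float = 4.0,
    n_points: int = 120,
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> OscSweep:
    """An oscillatory stress sweep with a plateau and power-law breakdown.

    G'(s) equals the plateau up to ``critical_stress`` and decays as
    (s / critical_stress)^-decay_exponent beyond it; G'' tracks G' at a
    constant phase angle. ``decay_exponent=0`` produces a flat sweep (no
    yield), exercising the no-yield error path downstream.
    """
    rng = np.random.default_rng(seed)
    s = np.logspace(math.log10(0.1), math.log10(1000.0), n_points)
    g1 = g_prime_plateau * np.minimum(1.0, (s / critical_stress) ** (-decay_exponent))
    if noise_cv > 0:
        g1 = g1 * (1.0 + rng.normal(0.0, noise_cv, n_points))
    g1 = np.maximum(g1, 1e-9)
    g2 = g1 * math.tan(math.radians(delta_deg))
    return OscSweep(points=tuple(zip(s, g1, g2)))


def gen_droplets(
    mean_um: float = 12.16,
    sd_um: float = 6.31,
    n: int = 500,
    seed: int = 0,
    batch_id: str = "batch",
) -> DropletSample:
    """Lognormal droplet diameters moment-matched to the target mean and SD."""
    rng = np.random.default_rng(seed)
    mu, sigma = lognormal_params(mean_um, sd_um)
    return DropletSample(
        batch_id=batch_id, diameters_um=tuple(rng.lognormal(mu, sigma, size=n))
    )


def gen_diffractogram(
    peak_sets: Sequence[PeakSet] = (),
    extra_peaks_deg: Sequence[float] = (),
    seed: int = 0,
    two_theta_range: tuple[float, float] = (3.0, 50.0),
    step_deg: float = 0.02,
    peak_height: float = 400.0,
    peak_sigma_deg: float = 0.08,
    hump_amplitude: float = 200.0,
    hump_center_deg: float = 20.0,
    hump_sigma_deg: float = 8.0,
    noise_sd: float = 5.0,
    background: float = 50.0,
) -> Diffractogram:
    """Gaussian reflections over a wide amorphous hump with additive noise.

    Peak positions come from the union of ``peak_sets`` plus any
    ``extra_peaks_deg``; ``noise_sd=0`` with no peaks yields a pure smooth
    hump (the no-peak control).
    """
    rng = np.random.default_rng(seed)
    lo, hi = two_theta_range
    tt = np.arange(lo, hi + step_deg / 2, step_deg)
    it = background + hump_amplitude * np.exp(
        -0.5 * ((tt - hump_center_deg) / hump_sigma_deg) ** 2
    )
    positions = [p for ps in peak_sets for p in ps.positions_deg]
    positions += list(extra_peaks_deg)
    for p in positions:
        it = it + peak_height * np.exp(-0.5 * ((tt - p) / peak_sigma_deg) ** 2)
    if noise_sd > 0:
        it = it + rng.normal(0.0, noise_sd, size=tt.size)
    it = np.maximum(it, 0.0)
    return Diffractogram(two_theta_deg=tuple(tt), intensity=tuple(it))
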
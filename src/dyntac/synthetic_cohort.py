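"""Synthetic dynamic-PET cohorts with known ground truth.

Everything downstream (kinetic fitting, feature extraction, selection,
stratification) is exercised on cohorts produced here, because no public
patient-level dynamic-PET dataset with outcomes exists. The generator knows
its own truth: kinetic parameters per ROI, the true free-component 10-30 min
slope in bone marrow, the standardized marker z, and the hazard used to draw
progression times.

Conventions
-----------
* t = 0 is tracer arrival at the start of the 65-min dynamic acquisition, so
  the 28-frame schedule spans 0-65 min and the 10/30/60-min feature anchors
  fall inside the scan.
* The input function is a tri-exponential bolus surrogate (Feng-style).
* Frame noise is zero-mean Gaussian with variance proportional to
  frame-value / frame-duration (standard dynamic-PET weighting), scaled so
  that ``noise_level`` is the fractional standard deviation at the TAC peak
  for a one-minute frame.
* Survival: exponential with hazard  baseline_hazard * exp(effect_size * z),
  z the standardized true bone-marrow C_f slope over 10-30 min; censoring is
  the minimum of an administrative cutoff and an independent uniform draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curves import FrameSchedule, TacCurve, frame_average
from .errors import InvalidInputError
from .kinetics import KineticParams, model_curves

__all__ = [
    "AifParams",
    "CohortSpec",
    "SurvivalRecord",
    "PatientSim",
    "Cohort",
    "gen_input_function",
    "simulate_patient",
    "gen_cohort",
    "gen_voxel_phantom",
    "slope_reference",
    "calibrate_baseline_hazard",
]

ROIS = ("tumor", "bone_marrow")


@dataclass(frozen=True)
class AifParams:
    """Tri-exponential bolus input function.

    C_b(t) = A1*tau*exp(-l1*tau) + A2*(exp(-l2*tau) - exp(-l1*tau))
           + A3*(exp(-l3*tau) - exp(-l1*tau)),   tau = t - t0  (0 before t0)

    Each term is non-negative whenever l1 > l2 > l3 >= 0 and amplitudes are
    non-negative, so the curve is non-negative with a single early peak for
    physiologic parameters.
    """

    A1: float = 300.0  # kBq/mL/min (linear-rise term)
    A2: float = 15.0  # kBq/mL
    A3: float = 8.0  # kBq/mL
    l1: float = 5.0  # 1/min
    l2: float = 0.25
    l3: float = 0.01
    t0: float = 0.5  # min

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 >= 0):
            raise InvalidInputError("decay rates must satisfy l1 > l2 > l3 >= 0")
        if self.A2 < 0 or self.A3 < 0:
            raise InvalidInputError("A2 and A3 must be >= 0")
        if self.t0 < 0:
            raise InvalidInputError("arrival delay t0 must be >= 0")


def gen_input_function(p: AifParams, times) -> TacCurve:
    """Evaluate the bolus input function on a minute grid."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be a strictly increasing 1-D grid")
    if t[0] < 0:
        raise InvalidInputError("times must be non-negative")
    tau = t - p.t0
    pos = tau > 0
    v = np.zeros_like(t)
    tp = tau[pos]
    e1 = np.exp(-p.l1 * tp)
    v[pos] = (
        p.A1 * tp * e1
        + p.A2 * (np.exp(-p.l2 * tp) - e1)
        + p.A3 * (np.exp(-p.l3 * tp) - e1)
    )
    return TacCurve(t, v, "blood")


# prior ranges (lo, hi) for each kinetic parameter, per ROI
DEFAULT_PRIORS = {
    "tumor": {
        "K1": (0.15, 0.45),
        "k2": (0.30, 0.90),
        "k3": (0.05, 0.20),
        "k4": (0.0, 0.008),
        "v_b": (0.03, 0.12),
    },
    "bone_marrow": {
        "K1": (0.04, 0.18),
        "k2": (0.15, 0.80),
        "k3": (0.01, 0.08),
        "k4": (0.0, 0.008),
        "v_b": (0.02, 0.08),
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort reproducibly."""

    n_patients: int = 32
    effect_size: float = -2.3  # log HR per 1 SD of the true BM C_f 10-30 slope
    baseline_hazard: float = 1.6e-3  # events/day at z = 0
    censor_admin_time: float = 900.0  # days
    censor_uniform_max: float = 1500.0  # days; independent U(0, max) censor draw
    noise_level: float = 0.05
    seed: int = 0
    priors: dict = field(default_factory=lambda: {r: dict(DEFAULT_PRIORS[r]) for r in ROIS})
    aif: AifParams = field(default_factory=AifParams)
    aif_scale_sd: float = 0.15  # lognormal sigma of per-patient amplitude jitter
    grid_dt_min: float = 0.01

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise InvalidInputError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise InvalidInputError("baseline_hazard must be > 0")
        if self.noise_level < 0:
            raise InvalidInputError("noise_level must be >= 0")
        if self.censor_admin_time <= 0 or self.censor_uniform_max <= 0:
            raise InvalidInputError("censoring times must be > 0")
        for roi, pri in self.priors.items():
            for name, (lo, hi) in pri.items():
                blo, bhi = {"K1": (0, 2), "k2": (0, 2), "k3": (0, 1), "k4": (0, 1), "v_b": (0, 1)}[name]
                if not (blo <= lo <= hi <= bhi):
                    raise InvalidInputError(f"prior range for {roi}.{name} out of bounds")

    @property
    def schedule(self) -> FrameSchedule:
        return FrameSchedule.default_28()

    def time_grid(self) -> np.ndarray:
        lo, hi = self.schedule.span_minutes
        n = int(round((hi - lo) / self.grid_dt_min))
        return np.linspace(lo, hi, n + 1)


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    pfs_days: float
    event: int
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PatientSim:
    """One simulated patient with full ground truth."""

    patient_id: str
    input_function: TacCurve
    true_params: dict  # roi -> KineticParams
    true_components: dict  # roi -> (C_f, C_m, C_T) dense TacCurves
    measured: dict  # roi -> TacCurve of noisy per-frame values at frame midpoints
    true_slope: float  # raw BM C_f slope over 10-30 min (kBq/mL/min)
    z: float  # standardized slope used in the hazard
    survival: SurvivalRecord
    voxels: dict = field(default_factory=dict)  # roi -> SUV array (1 mL voxels)


def _draw_params(pri: dict, rng: np.random.Generator) -> KineticParams:
    return KineticParams(**{k: float(rng.uniform(lo, hi)) for k, (lo, hi) in pri.items()})


def _cf_slope_10_30(cf: TacCurve) -> float:
    return (cf(30.0) - cf(10.0)) / 20.0


def slope_reference(spec: CohortSpec, n: int = 512) -> tuple[float, float]:
    """Prior-predictive mean and SD of the true BM C_f 10-30 min slope.

    Used to standardize the marker so the hazard model is well defined per
    patient (independent of who else is in the cohort). Deterministic given
    the spec's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA1F)))
    grid = spec.time_grid()
    aif = gen_input_function(spec.aif, grid)
    slopes = np.empty(n)
    for i in range(n):
        p = _draw_params(spec.priors["bone_marrow"], rng)
        cf, _, _ = model_curves(p, aif)
        slopes[i] = _cf_slope_10_30(cf)
    return float(np.mean(slopes)), float(np.std(slopes))


def _simulate_kinetics(spec: CohortSpec, rng: np.random.Generator, patient_id: str):
    grid = spec.time_grid()
    scale = float(np.exp(rng.normal(0.0, spec.aif_scale_sd)))
    aif_p = replace(
        spec.aif,
        A1=spec.aif.A1 * scale,
        A2=spec.aif.A2 * scale,
        A3=spec.aif.A3 * scale,
    )
    aif = gen_input_function(aif_p, grid)
    sched = spec.schedule
    mids = sched.mid_minutes
    d_min = sched.durations_min
    true_params, true_components, measured = {}, {}, {}
    for roi in ROIS:
        p = _draw_params(spec.priors[roi], rng)
        cf, cm, ct = model_curves(p, aif)
        frames = frame_average(ct, sched)
        peak = float(np.max(frames))
        # var_i = noise_level^2 * value_i * peak / duration_i(min):
        # noise_level is the fractional SD at the peak for a 1-minute frame
        sigma = spec.noise_level * np.sqrt(np.maximum(frames, 0.0) * peak / d_min)
        noisy = frames + rng.normal(0.0, 1.0, size=frames.size) * sigma
        true_params[roi] = p
        true_components[roi] = (cf, cm, ct)
        measured[roi] = TacCurve(mids, noisy, "measured")
    return aif, true_params, true_components, measured


def _draw_survival(spec: CohortSpec, z: float, rng: np.random.Generator) -> tuple[float, int]:
    hazard = spec.baseline_hazard * float(np.exp(spec.effect_size * z))
    t_event = rng.exponential(1.0 / hazard)
    c = min(spec.censor_admin_time, rng.uniform(0.0, spec.censor_uniform_max))
    time = min(t_event, c)
    return float(time), int(t_event <= c)


def _draw_clinical(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.round(rng.normal(56.0, 10.0), 1)),
        "sex": int(rng.integers(0, 2)),
        "smoking": int(rng.random() < 0.25),
    }


def simulate_patient(
    spec: CohortSpec,
    rng: np.random.Generator,
    z_norm: tuple[float, float] | None = None,
    patient_id: str = "P001",
) -> PatientSim:
    """Simulate one patient: TACs for both ROIs, ground truth, and survival.

    ``z_norm`` is the (mean, sd) used to standardize the true bone-marrow
    C_f slope; by default it comes from :func:`slope_reference` on the spec.
    """
    if z_norm is None:
        z_norm = slope_reference(spec)
    mu, sd = z_norm
    if sd <= 0:
        raise InvalidInputError("slope standardization SD must be > 0")
    aif, true_params, true_components, measured = _simulate_kinetics(spec, rng, patient_id)
    slope = _cf_slope_10_30(true_components["bone_marrow"][0])
    z = (slope - mu) / sd
    time, event = _draw_survival(spec, z, rng)
    covs = _draw_clinical(rng)
    voxels = {
        "tumor": rng.lognormal(mean=np.log(7.0), sigma=0.45, size=64),
        "bone_marrow": rng.lognormal(mean=np.log(1.5), sigma=0.35, size=64),
    }
    return PatientSim(
        patient_id=patient_id,
        input_function=aif,
        true_params=true_params,
        true_components=true_components,
        measured=measured,
        true_slope=slope,
        z=z,
        survival=SurvivalRecord(patient_id, time, event, covs),
        voxels=voxels,
    )


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    patients: list
    z_norm: tuple[float, float]

    @property
    def survival_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {"patient_id": p.patient_id, **p.survival.covariates,
                 "pfs_days": p.survival.pfs_days, "event": p.survival.event}
            )
        return pd.DataFrame(rows)

    @property
    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "true_slope": p.true_slope, "z": p.z}
            for roi in ROIS:
                kp = p.true_params[roi]
                for name in ("K1", "k2", "k3", "k4", "v_b"):
                    row[f"{roi}_{name}"] = getattr(kp, name)
            rows.append(row)
        return pd.DataFrame(rows)


def gen_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Generate a full cohort; optionally write the CSV/JSON artifacts.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    outputs.
    """
    z_norm = slope_reference(spec)
    ss = np.random.SeedSequence((spec.seed, 0xC0C0))
    children = ss.spawn(spec.n_patients)
    width = max(3, len(str(spec.n_patients)))
    patients = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:0{width}d}"
        patients.append(simulate_patient(spec, rng, z_norm=z_norm, patient_id=pid))
    cohort = Cohort(spec=spec, patients=patients, z_norm=z_norm)
    if out_dir is not None:
        from . import io as _io

        _io.write_cohort(cohort, out_dir)
    return cohort


def gen_voxel_phantom(
    n_voxels: int,
    voxel_volume_ml: float,
    suv_rule: float | Callable[[np.random.Generator, int], np.ndarray] = 3.0,
    seed: int = 0,
    threshold: float = 2.5,
):
    """Voxel SUV phantom with closed-form MTV/TLG ground truth.

    ``suv_rule`` is either a constant SUV or a callable ``(rng, n) -> array``.
    Returns ``(suv_array, truth)`` where truth holds the exact MTV (mL) and
    TLG (mL*SUV) at the given threshold.
    """
    if n_voxels < 1:
        raise InvalidInputError("n_voxels must be >= 1")
    if voxel_volume_ml <= 0:
        raise InvalidInputError("voxel volume must be > 0")
    rng = np.random.default_rng(seed)
    if callable(suv_rule):
        suv = np.asarray(suv_rule(rng, n_voxels), dtype=float)
        if suv.shape != (n_voxels,):
            raise InvalidInputError("suv_rule must return an array of length n_voxels")
    else:
        suv = np.full(n_voxels, float(suv_rule))
    above = suv >= threshold
    mtv = float(above.sum() * voxel_volume_ml)
    tlg = float(mtv * suv[above].mean()) if above.any() else 0.0
    return suv, {"mtv_ml": mtv, "tlg": tlg, "n_above": int(above.sum()), "threshold": threshold}


def expected_event_fraction(
    spec: CohortSpec, baseline_hazard: float, n_mc: int = 20000, seed: int = 12345
) -> float:
    """Monte-Carlo expected event fraction for a candidate baseline hazard."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_mc)
    u = rng.random(n_mc)
    c = np.minimum(spec.censor_admin_time, rng.uniform(0.0, spec.censor_uniform_max, n_mc))
    h = baseline_hazard * np.exp(spec.effect_size * z)
    t = -np.log(u) / h
    return float(np.mean(t <= c))


def calibrate_baseline_hazard(
    spec: CohortSpec, target_event_frac: float = 17.0 / 32.0, n_mc: int = 20000
) -> CohortSpec:
    """Tune the baseline hazard so the expected event fraction hits a target.

    Uses common random numbers so the objective is a smooth, monotone
    function of the hazard, then solves by bisection.
    """
    if not 0 < target_event_frac < 1:
        raise InvalidInputError("target_event_frac must be in (0,1)")

    def f(log_h):
        return expected_event_fraction(spec, float(np.exp(log_h)), n_mc=n_mc) - target_event_frac

    lo, hi = np.log(1e-7), np.log(1.0)
    log_h = brentq(f, lo, hi, xtol=1e-10)
    return replace(spec, baseline_hazard=float(np.exp(log_h)))
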
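"""Synthetic phantom-and-cohort generator.

The trial this pipeline models deposits no public imaging data, so every
downstream stage is exercised on synthetic inputs with the same statistical
structure:

* **Phantoms** — an ellipsoidal gross tumor volume (GTV) inside a brain-sized
  grid, with activity laid down as isotropic Gaussian kernels centered on
  1–4 catheter tips (convection-enhanced delivery deposits drug around the
  infusing tip; a Gaussian is the simplest smooth model with analytic
  support), scaled so the voxel sum equals the administered end-of-infusion
  (EOI) activity.
* **Imaging series** — expected voxel counts decay purely physically with the
  Re-186 half-life (89.2 h) across the imaging schedule {0, 24, 120, 192} h
  post-EOI; observed counts are Poisson; each frame carries a standard-source
  vial record for calibration.  No biological clearance from brain by
  default (the modeled trial observed persistent local retention).
* **Outcomes** — lognormal accelerated-failure-time survival with absorbed
  dose and tumor-coverage effects plus age/ECOG/baseline-volume covariates,
  administrative right-censoring; CTCAE-graded adverse-event tables with
  grade and attribution frequencies defaulting to the trial's empirical
  event-level proportions.

The dose-escalation plan, per-cohort demographics and AE frequencies default
to the published per-cohort tables in :mod:`cedose.trial_tables`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import trial_tables as tt
from .dosimetry import DecayModel
from .quant import ActivityVolume, StandardSource

#: Default post-EOI imaging schedule, hours.
DEFAULT_IMAGING_TIMES_H = (0.0, 24.0, 120.0, 192.0)

#: Default detector sensitivity: expected whole-image counts per mCi in the
#: field of view.  5e5 gives ~0.5M counts for a 1 mCi infusion — a realistic
#: total for a quantitative brain SPECT acquisition.
DEFAULT_COUNTS_PER_MCI = 5.0e5

AE_TERMS_CNS = (
    "headache",
    "seizure",
    "edema cerebral",
    "memory impairment",
    "dysphasia",
    "gait disturbance",
    "dizziness",
)
AE_TERMS_SYSTEMIC = (
    "fatigue",
    "nausea",
    "vomiting",
    "diarrhea",
    "constipation",
    "anorexia",
    "alanine aminotransferase increased",
    "edema limbs",
    "tinnitus",
)


@dataclass
class PhantomSpec:
    """Geometry of one synthetic patient: grid, tumor ellipsoid, catheters."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    tumor_radii_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    catheter_tips: tuple[tuple[float, float, float], ...] = ((32.0, 32.0, 32.0),)
    kernel_sigma_mm: float = 14.0
    background_fraction: float = 0.02

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be positive")
        if self.kernel_sigma_mm <= 0:
            raise ValueError("kernel sigma must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0,1)")
        if not 1 <= len(self.catheter_tips) <= 4:
            raise ValueError(f"need 1..4 catheter tips, got {len(self.catheter_tips)}")
        for axis in range(3):
            r_vox = self.tumor_radii_mm[axis] / self.voxel_size_mm[axis]
            c = self.tumor_center[axis]
            if c - r_vox < 0 or c + r_vox > self.grid_shape[axis] - 1:
                raise ValueError("tumor ellipsoid does not fit inside the grid")
        for tip in self.catheter_tips:
            for axis in range(3):
                if not 0 <= tip[axis] <= self.grid_shape[axis] - 1:
                    raise ValueError(f"catheter tip {tip} lies outside the grid")


def _coordinate_grids_mm(spec: PhantomSpec) -> list[np.ndarray]:
    idx = np.indices(spec.grid_shape, dtype=float)
    return [idx[a] * spec.voxel_size_mm[a] for a in range(3)]


def make_phantom(
    spec: PhantomSpec,
    total_activity_mCi: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (tumor_mask, true_activity_mCi) for one patient.

    The activity field is the sum of isotropic Gaussian kernels at the
    catheter tips (plus a uniform background carrying
    ``background_fraction`` of the total), normalized so the voxel sum
    equals ``total_activity_mCi`` exactly.  Construction is deterministic;
    ``seed`` is accepted for interface symmetry with the stochastic stages.
    """
    del seed  # deterministic construction
    if total_activity_mCi <= 0:
        raise ValueError("total activity must be positive")
    grids = _coordinate_grids_mm(spec)
    kernels = np.zeros(spec.grid_shape, dtype=float)
    two_s2 = 2.0 * spec.kernel_sigma_mm**2
    for tip in spec.catheter_tips:
        d2 = sum(
            (grids[a] - tip[a] * spec.voxel_size_mm[a]) ** 2 for a in range(3)
        )
        kernels += np.exp(-d2 / two_s2)
    kernels /= kernels.sum()
    activity = (1.0 - spec.background_fraction) * kernels
    if spec.background_fraction > 0:
        activity = activity + spec.background_fraction / kernels.size
    activity *= total_activity_mCi / activity.sum()

    e2 = sum(
        ((grids[a] - spec.tumor_center[a] * spec.voxel_size_mm[a]) / spec.tumor_radii_mm[a]) ** 2
        for a in range(3)
    )
    tumor_mask = e2 <= 1.0
    return tumor_mask, activity


def simulate_imaging_series(
    activity_mCi: np.ndarray,
    voxel_size_mm: Sequence[float],
    times_h: Sequence[float] = DEFAULT_IMAGING_TIMES_H,
    counts_per_mCi: float = DEFAULT_COUNTS_PER_MCI,
    seed: int | None = 0,
    noise: bool = True,
    vial_mCi: float = 1.0,
    model: DecayModel = DecayModel(),
) -> list[ActivityVolume]:
    """Image a true EOI activity field at a series of post-EOI time points.

    Expected voxel counts at time t are ``activity x 2^(-t/T_half) x
    counts_per_mCi``; observed counts are Poisson unless ``noise=False``.
    Each frame carries a synthetic standard-source record: a vial of
    ``vial_mCi`` at EOI, decayed to the acquisition time, with its own
    (optionally Poisson) measured counts.
    """
    if counts_per_mCi <= 0:
        raise ValueError("counts_per_mCi must be positive")
    times = [float(t) for t in times_h]
    if any(t < 0 for t in times):
        raise ValueError("imaging times must be >= 0 relative to EOI")
    rng = np.random.default_rng(seed)
    frames = []
    for t in times:
        factor = model.decay_factor(t)
        expected = activity_mCi * factor * counts_per_mCi
        counts = rng.poisson(expected).astype(float) if noise else expected
        vial_now = vial_mCi * factor
        vial_expected = vial_now * counts_per_mCi
        vial_counts = float(rng.poisson(vial_expected)) if noise else vial_expected
        frames.append(
            ActivityVolume(
                counts=counts,
                voxel_size_mm=tuple(voxel_size_mm),
                time_h=t,
                calibration=StandardSource(vial_now, max(vial_counts, 1.0)),
            )
        )
    return frames


@dataclass
class SurvivalSimParams:
    """Lognormal AFT generating model for OS/PFS.

    Dose and coverage effects default to the adjusted fold changes reported
    for overall survival in the modeled trial: +27% OS per 10 percentage
    points of tumor coverage (beta = ln 1.274 / 10 per %) and +31% per 100 Gy
    (beta = ln 1.312 / 100 per Gy).  The intercept and the remaining
    covariate effects are set so a cohort-average patient has a median OS
    near 11 months; sigma_log = 0.8 is a typical log-scale spread for
    recurrent glioblastoma survival.
    """

    beta_coverage_per_pct: float = math.log(1.274) / 10.0
    beta_dose_per_Gy: float = math.log(1.312) / 100.0
    beta_age_per_y: float = -0.010
    beta_ecog: float = -0.30
    beta_volume_per_mL: float = -0.020
    sigma_log: float = 0.80
    intercept: float = 1.12
    censor_time_months: float = 36.0
    pfs_log_shift: float = math.log(4.0 / 11.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.censor_time_months <= 0:
            raise ValueError("censor time must be > 0")


def linear_predictor(patients: pd.DataFrame, params: SurvivalSimParams) -> np.ndarray:
    """Xb for the survival model (shared by OS and PFS)."""
    return (
        params.intercept
        + params.beta_coverage_per_pct * patients["tvt_percent"].to_numpy()
        + params.beta_dose_per_Gy * patients["absorbed_dose_Gy"].to_numpy()
        + params.beta_age_per_y * patients["age_y"].to_numpy()
        + params.beta_ecog * patients["ecog"].to_numpy()
        + params.beta_volume_per_mL * patients["baseline_tumor_mL"].to_numpy()
    )


def simulate_outcomes(patients: pd.DataFrame, params: SurvivalSimParams) -> pd.DataFrame:
    """Attach OS/PFS and best response to a per-patient dosimetry table.

    ``patients`` needs columns tvt_percent, absorbed_dose_Gy, age_y, ecog,
    baseline_tumor_mL.  log T = intercept + Xb + sigma eps with standard
    normal eps; administrative right-censoring at ``censor_time_months``.
    PFS shares the linear predictor with a negative log shift and is clipped
    at OS (progression is observed no later than death).  Best response is
    drawn with stable-disease odds increasing in coverage.
    """
    rng = np.random.default_rng(params.seed)
    n = len(patients)
    xb = linear_predictor(patients, params)
    out = patients.copy()

    os_t = np.exp(xb + params.sigma_log * rng.standard_normal(n))
    out["os_months"] = np.minimum(os_t, params.censor_time_months)
    out["os_event"] = os_t <= params.censor_time_months

    pfs_t = np.exp(xb + params.pfs_log_shift + params.sigma_log * rng.standard_normal(n))
    pfs_t = np.minimum(pfs_t, os_t)
    out["pfs_months"] = np.minimum(pfs_t, params.censor_time_months)
    out["pfs_event"] = pfs_t <= params.censor_time_months

    # Best response: higher coverage shifts mass from PD toward SD/PR.
    cov = patients["tvt_percent"].to_numpy() / 100.0
    p_pr = 0.02 + 0.08 * cov
    p_sd = 0.25 + 0.45 * cov
    p_pd = np.clip(1.0 - p_pr - p_sd, 0.0, None)
    probs = np.stack([np.zeros(n), p_pr, p_sd, p_pd], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    cats = np.array(["CR", "PR", "SD", "PD"])
    out["best_response"] = [cats[rng.choice(4, p=p)] for p in probs]
    return out


@dataclass
class AESimParams:
    """Adverse-event generator: grade/relation multinomials default to the
    modeled trial's event-level proportions (159 events over 21 patients)."""

    mean_events_per_patient: float = 159.0 / 21.0
    grade_probs: tuple[float, float, float] = (114 / 159, 34 / 159, 11 / 159)
    relation_probs: tuple[float, float, float, float, float] = (
        1 / 159,   # definite
        1 / 159,   # probable
        20 / 159,  # possible
        28 / 159,  # unlikely
        109 / 159, # unrelated
    )
    p_cns_term: float = 0.45
    dlt_free: bool = True
    seed: int = 0


RELATION_LABELS = ("definite", "probable", "possible", "unlikely", "unrelated")


def simulate_adverse_events(patients: pd.DataFrame, params: AESimParams) -> pd.DataFrame:
    """CTCAE-graded AE table (one row per event, not deduplicated).

    With ``dlt_free=True`` (the modeled trial observed no dose-limiting
    toxicity) any attributable grade-3 draw is downgraded to unlikely
    attribution, so the escalation replay sees 0 DLTs.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for _, p in patients.iterrows():
        n_ev = rng.poisson(params.mean_events_per_patient)
        for _ in range(n_ev):
            cns = rng.random() < params.p_cns_term
            term = rng.choice(AE_TERMS_CNS if cns else AE_TERMS_SYSTEMIC)
            grade = int(rng.choice([1, 2, 3], p=params.grade_probs))
            relation = str(rng.choice(RELATION_LABELS, p=params.relation_probs))
            if params.dlt_free and grade >= 3 and relation in ("possible", "probable", "definite"):
                relation = "unlikely"
            onset = float(rng.uniform(0, 60))
            duration_d = float(rng.exponential(7.0))
            rows.append(
                {
                    "patient_id": p["id"],
                    "cohort": int(p["cohort"]),
                    "term": term,
                    "grade": grade,
                    "relation": relation,
                    "cns": cns,
                    "onset_day": onset,
                    "resolution_day": onset + duration_d,
                    "serious": bool(grade >= 3 and rng.random() < 0.5),
                }
            )
    return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_covariates(seed: int = 0, plan: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient dosing and baseline covariates following the escalation
    plan and per-cohort demographics of the modeled trial."""
    plan = tt.COHORT_PLAN if plan is None else plan
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, prow in plan.iterrows():
        ages = tt.COHORT_AGE_STATS.loc[cohort]
        vols = tt.COHORT_TUMOR_VOLUME_STATS.loc[cohort]
        ecog_counts = tt.COHORT_ECOG_COUNTS.loc[cohort]
        ecog_p = ecog_counts / ecog_counts.sum()
        for k in range(int(prow["n_patients"])):
            # cohorts 1-3 used a single catheter; later cohorts used 1-4
            n_cath = 1 if cohort <= 3 else int(rng.choice([1, 2, 3, 4], p=[0.4, 0.25, 0.2, 0.15]))
            rows.append(
                {
                    "id": f"C{cohort}P{k + 1}",
                    "cohort": int(cohort),
                    "administered_mCi": float(prow["administered_mCi"]),
                    "infused_mL": float(prow["infused_volume_mL"]),
                    "n_catheters": n_cath,
                    "age_y": float(
                        _truncated_normal(rng, ages["mean_y"], ages["sd_y"], ages["min_y"], ages["max_y"])
                    ),
                    "ecog": int(rng.choice([0, 1, 2], p=ecog_p.to_numpy())),
                    "baseline_tumor_mL": float(
                        _truncated_normal(rng, vols["mean_mL"], vols["sd_mL"], vols["min_mL"], vols["max_mL"])
                    ),
                }
            )
    return pd.DataFrame(rows)


def phantom_for_patient(
    patient: pd.Series,
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    kernel_sigma_mm: float | None = None,
    p_poor_placement: float = 0.15,
) -> PhantomSpec:
    """PhantomSpec for one patient: a near-spherical GTV of the patient's
    baseline volume at grid center, catheter tips jittered around it.

    Per-patient kernel spread is drawn uniformly on 12–20 mm unless fixed,
    so single-catheter treated volumes land in the tens of mL.  With
    probability ``p_poor_placement`` a tip is grossly displaced (1.5–2.5
    tumor radii off-center), emulating the occasional poorly-converged
    infusion that yields low tumor coverage.
    """
    r_mm = (3.0 * patient["baseline_tumor_mL"] * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    # mild anisotropy so masks are not exact spheres
    stretch = rng.uniform(0.85, 1.15, size=3)
    stretch /= stretch.prod() ** (1.0 / 3.0)
    radii = tuple(float(r_mm * s) for s in stretch)
    center = tuple((n - 1) / 2.0 for n in grid_shape)
    half_extent = np.asarray(grid_shape) / 2.0 * np.asarray(voxel_size_mm)
    if kernel_sigma_mm is None:
        kernel_sigma_mm = float(rng.uniform(12.0, 20.0))
    tips = []
    for _ in range(int(patient["n_catheters"])):
        if rng.random() < p_poor_placement:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            offset_mm = direction * rng.uniform(1.5, 2.5) * np.asarray(radii)
        else:
            offset_mm = rng.uniform(-0.9, 0.9, size=3) * np.asarray(radii)
        offset_mm = np.clip(offset_mm, -0.9 * half_extent, 0.9 * half_extent)
        tips.append(
            tuple(center[a] + offset_mm[a] / voxel_size_mm[a] for a in range(3))
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        tumor_center=center,
        tumor_radii_mm=radii,
        catheter_tips=tuple(tips),
        kernel_sigma_mm=kernel_sigma_mm,
    )


def simulate_urine_samples(
    administered_mCi: float,
    leak_fractions: Sequence[tuple[float, float, float]] = ((0.0, 24.0, 0.10), (24.0, 48.0, 0.02)),
    counts_per_mCi: float = DEFAULT_COUNTS_PER_MCI,
    model: DecayModel = DecayModel(),
) -> list[tuple[float, float, float, float]]:
    """Noiseless urine collection records for a monoexponential-leak patient.

    Each (t0, t1, fraction) becomes a counted sample whose measured counts
    reflect physical decay at the collection end time, so decay-correcting
    back to administration recovers exactly ``fraction x administered``.
    """
    samples = []
    for t0, t1, frac in leak_fractions:
        activity_at_t1 = frac * administered_mCi * model.decay_factor(t1)
        samples.append((t0, t1, activity_at_t1 * counts_per_mCi, counts_per_mCi))
    return samples
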
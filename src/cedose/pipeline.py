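"""Pipeline orchestration: synthetic cohort -> SPECT quantification ->
dosimetry -> outcomes -> safety, under one seeded config.

Every output table is stamped (in the results bundle) with the config hash,
seed, and the physical constants in effect (dose constant 7.126
Gy·g/(mCi·h), half-life 89.2 h, threshold fraction).  Reruns with the same
config and seed are byte-identical; changing only the seed changes only the
stochastic outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import trial_tables as tt
from .dosimetry import (
    DOSE_CONSTANT_GY_G_PER_MCI_H,
    DecayModel,
    TimeActivityCurve,
    cumulated_activity,
    dose_summary,
)
from .outcomes import (
    aft_lognormal_fit,
    cohort_summary,
    correlation_screen,
    km_fit,
    logrank,
    response_table,
)
from .quant import DEFAULT_THRESHOLD_FRACTION, quantify_frame, whole_image_scale_correction, calibrate_counts
from .safety import count_dlts, grade_relation_summary, patient_frequency_table, replay_escalation
from .synthetic import (
    AESimParams,
    DEFAULT_COUNTS_PER_MCI,
    DEFAULT_IMAGING_TIMES_H,
    SurvivalSimParams,
    make_phantom,
    phantom_for_patient,
    simulate_adverse_events,
    simulate_covariates,
    simulate_imaging_series,
    simulate_outcomes,
)

log = logging.getLogger("cedose")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


@dataclass
class RunConfig:
    """Single structured config for an end-to-end run."""

    output_dir: Path = Path("cedose_run")
    seed: int = 1
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    half_life_h: float = 89.2
    integration_end_h: float = 192.0
    tail: str = "none"
    dichotomy_Gy: float = 100.0
    tvt_report_time_h: float = 120.0
    counts_per_mCi: float = DEFAULT_COUNTS_PER_MCI
    imaging_times_h: tuple[float, ...] = DEFAULT_IMAGING_TIMES_H
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    kernel_sigma_mm: float | None = None  # None -> per-patient draw on 12-20 mm
    noise: bool = True
    covariates: tuple[str, ...] = (
        "tvt_percent",
        "absorbed_dose_Gy",
        "age_y",
        "ecog",
        "baseline_tumor_mL",
    )
    write_volumes: bool = False

    def validate(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ConfigError(f"threshold_fraction must be in (0,1), got {self.threshold_fraction}")
        if self.half_life_h <= 0 or self.integration_end_h <= 0 or self.dichotomy_Gy <= 0:
            raise ConfigError("half_life_h, integration_end_h, dichotomy_Gy must be > 0")
        if self.tail not in ("none", "physical_decay"):
            raise ConfigError(f"tail must be 'none' or 'physical_decay', got {self.tail!r}")
        if self.tvt_report_time_h not in self.imaging_times_h:
            raise ConfigError(
                f"tvt_report_time_h={self.tvt_report_time_h} is not an imaging time"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds (< 2^31) derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_patient_images(
    patient: pd.Series,
    cfg: RunConfig,
    rng: np.random.Generator,
    frame_seed: int,
):
    """Phantom + imaging series for one patient.  Returns (spec, gtv, series)."""
    spec = phantom_for_patient(
        patient,
        rng,
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        kernel_sigma_mm=cfg.kernel_sigma_mm,
    )
    gtv_mask, activity = make_phantom(spec, total_activity_mCi=patient["administered_mCi"])
    series = simulate_imaging_series(
        activity,
        cfg.voxel_size_mm,
        times_h=cfg.imaging_times_h,
        counts_per_mCi=cfg.counts_per_mCi,
        seed=frame_seed,
        noise=cfg.noise,
        model=DecayModel(cfg.half_life_h),
    )
    return spec, gtv_mask, series


def quantify_patient(series, gtv_mask, cfg: RunConfig, administered_mCi: float) -> pd.DataFrame:
    """Per-timepoint quantification for one patient's imaging series.

    The EOI frame defines the shared whole-image scale factor (total activity
    validated against the administered activity); each frame is thresholded
    and coverage metrics recorded.  The tumor count fraction is kept so the
    dosimetry stage can rebuild the time-activity curve from this table.
    """
    eoi = min(series, key=lambda v: v.time_h)
    if eoi.time_h != 0:
        raise ValueError("series must include an EOI frame at t=0")
    eoi_activity, _ = calibrate_counts(eoi)
    _, scale = whole_image_scale_correction(eoi_activity, administered_mCi)
    rows = []
    for vol in sorted(series, key=lambda v: v.time_h):
        activity, total_mCi, region = quantify_frame(
            vol, gtv_mask, cfg.threshold_fraction, scale_factor=scale
        )
        rows.append(
            {
                "time_h": vol.time_h,
                "total_mCi": total_mCi,
                "tumor_count_fraction": float(vol.counts[gtv_mask].sum() / vol.counts.sum()),
                "vd_mL": region.vd_mL,
                "gtv_mL": region.gtv_mL,
                "tvt_percent": region.tvt_percent,
                "eoi_scale_factor": scale,
            }
        )
    return pd.DataFrame(rows)


def dose_from_quant(frames: pd.DataFrame, cfg: RunConfig) -> dict:
    """Tumor dosimetry from one patient's per-timepoint quantification table."""
    tac = TimeActivityCurve(
        frames["time_h"].to_numpy(),
        (frames["tumor_count_fraction"] * frames["total_mCi"]).to_numpy(),
    )
    a_cum = cumulated_activity(
        tac, end_h=cfg.integration_end_h, tail=cfg.tail, model=DecayModel(cfg.half_life_h)
    )
    gtv_mL = float(frames["gtv_mL"].iloc[0])
    tvt = float(
        frames.loc[frames["time_h"] == cfg.tvt_report_time_h, "tvt_percent"].iloc[0]
    )
    ds = dose_summary(a_cum, gtv_mL, tvt_percent=tvt, dichotomy_Gy=cfg.dichotomy_Gy)
    return {
        "cumulated_mCi_h": ds.cumulated_mCi_h,
        "tumor_mass_g": ds.tumor_mass_g,
        "absorbed_dose_Gy": ds.absorbed_dose_Gy,
        "ge_100Gy": ds.ge_100Gy,
        "tvt_percent": ds.tvt_percent,
        "vd_mL_at_report": float(
            frames.loc[frames["time_h"] == cfg.tvt_report_time_h, "vd_mL"].iloc[0]
        ),
    }


def run_outcomes_analyses(records: pd.DataFrame, cfg: RunConfig) -> dict:
    """The trial-style outcome battery on a completed patient table."""
    results: dict = {}
    for endpoint in ("os", "pfs"):
        t, e = records[f"{endpoint}_months"], records[f"{endpoint}_event"]
        km = km_fit(t, e, landmark_times=(9.0,))
        results[f"km_{endpoint}"] = {
            "median_months": km.median_months,
            "ci95_months": km.median_ci95,
            "n": km.n,
            "events": km.events,
            "S_at_9_months": km.landmarks[9.0],
        }
    hi = records["absorbed_dose_Gy"] >= cfg.dichotomy_Gy
    results["n_ge_dichotomy"] = int(hi.sum())
    for endpoint in ("os", "pfs"):
        t, e = f"{endpoint}_months", f"{endpoint}_event"
        km_hi = km_fit(records.loc[hi, t], records.loc[hi, e])
        km_lo = km_fit(records.loc[~hi, t], records.loc[~hi, e])
        chi2, p = logrank(
            records.loc[hi, t], records.loc[hi, e], records.loc[~hi, t], records.loc[~hi, e]
        )
        results[f"{endpoint}_by_dose_group"] = {
            "dichotomy_Gy": cfg.dichotomy_Gy,
            "median_ge_months": km_hi.median_months,
            "median_lt_months": km_lo.median_months,
            "logrank_chi2": chi2,
            "logrank_p": p,
        }
    increments = {"tvt_percent": 10.0, "absorbed_dose_Gy": 100.0}
    for endpoint in ("OS", "PFS"):
        fit = aft_lognormal_fit(
            records, list(cfg.covariates), endpoint=endpoint, increments=increments
        )
        results[f"aft_{endpoint.lower()}"] = {
            "coefficients": fit.coefficients.to_dict(),
            "sigma": fit.sigma,
            "log_likelihood": fit.log_likelihood,
            "fold_changes": fit.fold_changes.reset_index().to_dict(orient="records"),
        }
    results["correlations"] = correlation_screen(
        records,
        pairs=[
            ("absorbed_dose_Gy", "tvt_percent"),
            ("absorbed_dose_Gy", "infused_mL"),
            ("absorbed_dose_Gy", "age_y"),
            ("absorbed_dose_Gy", "baseline_tumor_mL"),
            ("n_catheters", "vd_mL_at_report"),
            ("n_catheters", "infused_mL"),
        ],
    ).to_dict(orient="records")
    resp = response_table(records)
    results["response"] = {
        "overall_counts": resp["overall_counts"].to_dict(),
        "overall_percent": resp["overall_percent"].to_dict(),
        "orr_percent": resp["orr_percent"],
    }
    demo = cohort_summary(records)
    results["demographics"] = {
        col: {"pooled": demo["continuous"][col]["pooled"]} for col in demo["continuous"]
    }
    return results


def run_safety_analyses(ae_table: pd.DataFrame, records: pd.DataFrame) -> dict:
    """Safety battery: dedup tables, grade/relation summary, DLTs, 3+3 replay."""
    n_patients = len(records)
    freq = patient_frequency_table(ae_table, n_patients)
    summary = grade_relation_summary(events=ae_table)
    dlts = count_dlts(ae_table)
    cohort_sizes = records.groupby("cohort").size()
    history = [
        (int(c), int(cohort_sizes.loc[c]), int(dlts["n_dlt"].get(c, 0)))
        for c in sorted(cohort_sizes.index)
    ]
    escalation = replay_escalation(history)
    return {
        "patient_frequency": freq.reset_index().to_dict(orient="records"),
        "grade_overall_percent": summary["grade_overall_percent"].to_dict(),
        "relation_overall_percent": summary["relation_overall_percent"].to_dict(),
        "n_events": summary["n_events"],
        "n_dlt_total": int(dlts["n_dlt"].sum()),
        "escalation": escalation,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic end-to-end pipeline and write the bundle.

    Stages: simulate covariates/phantoms/images -> quantify -> dosimetry ->
    simulated outcomes + analyses -> simulated AEs + safety analyses.
    Returns the results bundle (also written as JSON under ``output_dir``).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg.seed, 4)
    cov_seed, img_seed, outcome_seed, ae_seed = seeds
    log.info("simulating cohort (seed %d)", cfg.seed)

    patients = simulate_covariates(seed=cov_seed)
    geom_rng = np.random.default_rng(cov_seed + 1)
    frame_seeds = _spawn_seeds(img_seed, len(patients))

    quant_rows, dose_rows = [], []
    for i, (_, patient) in enumerate(patients.iterrows()):
        spec, gtv, series = simulate_patient_images(patient, cfg, geom_rng, frame_seeds[i])
        if cfg.write_volumes:
            vdir = out / "volumes"
            cio.save_nifti(gtv, cfg.voxel_size_mm, vdir / f"{patient['id']}_gtv.nii")
            cio.save_nifti(
                series[0].counts, cfg.voxel_size_mm, vdir / f"{patient['id']}_eoi_counts.nii"
            )
        frames = quantify_patient(series, gtv, cfg, patient["administered_mCi"])
        frames.insert(0, "id", patient["id"])
        quant_rows.append(frames)
        dose_rows.append({"id": patient["id"], **dose_from_quant(frames, cfg)})

    quant_table = pd.concat(quant_rows, ignore_index=True)
    dose_table = pd.DataFrame(dose_rows)
    records = patients.merge(dose_table, on="id")

    records = simulate_outcomes(
        records, SurvivalSimParams(seed=outcome_seed)
    )
    ae_table = simulate_adverse_events(records, AESimParams(seed=ae_seed))

    outcome_results = run_outcomes_analyses(records, cfg)
    safety_results = run_safety_analyses(ae_table, records)

    cio.write_table(quant_table, out / "quantification_per_timepoint.csv")
    cio.write_table(dose_table, out / "dosimetry_per_patient.csv")
    cio.write_table(records, out / "patients.csv")
    cio.write_table(ae_table, out / "adverse_events.csv")

    bundle = {
        "config": cfg.to_dict(),
        "config_hash": cio.config_hash(cfg.to_dict()),
        "seed": cfg.seed,
        "constants": {
            "dose_constant_Gy_g_per_mCi_h": DOSE_CONSTANT_GY_G_PER_MCI_H,
            "half_life_h": cfg.half_life_h,
            "threshold_fraction": cfg.threshold_fraction,
            "dichotomy_Gy": cfg.dichotomy_Gy,
        },
        "outcomes": outcome_results,
        "safety": safety_results,
    }
    cio.write_json(bundle, out / "results_bundle.json")
    cio.write_manifest(
        {
            "patients_csv": "patients.csv",
            "quantification_csv": "quantification_per_timepoint.csv",
            "dosimetry_csv": "dosimetry_per_patient.csv",
            "adverse_events_csv": "adverse_events.csv",
            "results_bundle": "results_bundle.json",
            "config_hash": bundle["config_hash"],
        },
        out / "manifest.yaml",
    )
    return bundle
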
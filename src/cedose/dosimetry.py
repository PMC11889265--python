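"""MIRD-style local-deposition dosimetry for an intracranially delivered
beta emitter.

The dose model assumes 100% of the beta energy is deposited locoregionally
and neglects the gamma component (for rhenium-186 the gamma exposure is small
relative to its beta dose; the ~1.8 mm mean beta path length justifies local
deposition at tumor scale).  Absorbed dose to a region of mass *m* grams with
cumulated activity *A~* (mCi·h) is

    D [Gy] = 7.126 x A~ / m

with 7.126 in Gy·g/(mCi·h), the equilibrium dose constant for the Re-186
beta spectrum.  Tumor mass is volume x 1 g/mL.  Cumulated activity is the
trapezoidal integral of the region time-activity curve over the imaging
window (default 0–192 h post end-of-infusion, with no decay tail unless
requested).

Physical decay uses the Re-186 half-life of 89.2 h throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .quant import ActivityVolume, calibrate_counts

#: Equilibrium dose constant for the Re-186 beta spectrum, Gy·g/(mCi·h).
DOSE_CONSTANT_GY_G_PER_MCI_H = 7.126

#: Physical half-life of Re-186, hours.
RE186_HALF_LIFE_H = 89.2

#: Assumed soft-tissue density for mass-from-volume conversion, g/mL.
TISSUE_DENSITY_G_PER_ML = 1.0

#: Default cumulated-activity integration window, hours post-EOI.
DEFAULT_INTEGRATION_END_H = 192.0


@dataclass(frozen=True)
class DecayModel:
    """Pure physical decay with a fixed half-life (hours)."""

    half_life_h: float = RE186_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError(f"half-life must be > 0, got {self.half_life_h}")

    @property
    def lambda_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    def decay_factor(self, dt_h: float) -> float:
        """Fraction of activity remaining after ``dt_h`` hours."""
        return math.exp(-self.lambda_per_h * dt_h)


@dataclass
class TimeActivityCurve:
    """Ordered (time_h, activity_mCi) samples for one region, t=0 at EOI."""

    times_h: np.ndarray
    activities_mCi: np.ndarray
    region_label: str = "tumor"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_mCi = np.asarray(self.activities_mCi, dtype=float)
        if self.times_h.shape != self.activities_mCi.shape or self.times_h.ndim != 1:
            raise ValueError("times and activities must be 1D arrays of equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.activities_mCi < 0):
            raise ValueError("activities must be nonnegative")


@dataclass
class DoseSummary:
    """Per-patient tumor dosimetry result."""

    cumulated_mCi_h: float
    tumor_mass_g: float
    absorbed_dose_Gy: float
    ge_100Gy: bool
    tvt_percent: float | None = None


def decay_correct(
    activity_mCi: float,
    from_time_h: float,
    to_time_h: float,
    model: DecayModel = DecayModel(),
) -> float:
    """Decay-correct an activity measured at ``from_time_h`` to ``to_time_h``.

    Correcting to an earlier time increases the value: the returned quantity
    is activity x exp(lambda x (from - to)).
    """
    return activity_mCi * math.exp(model.lambda_per_h * (from_time_h - to_time_h))


def build_tac(
    series: Sequence[ActivityVolume],
    region_mask: np.ndarray,
    scale_factor: float | None = None,
    region_label: str = "tumor",
) -> TimeActivityCurve:
    """Region time-activity curve from a calibrated imaging series.

    Per frame, region activity = (region counts / whole-image counts) x
    whole-image activity from the standard-source calibration — the whole
    brain is the reference compartment, so the ratio is robust to count-rate
    scaling.  ``scale_factor`` is the shared EOI whole-image correction.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if len(series) < 2:
        raise ValueError("need at least 2 time points to build a time-activity curve")
    times, acts = [], []
    for vol in series:
        total_counts = vol.counts.sum()
        if total_counts <= 0:
            raise ValueError(f"whole-brain counts are 0 at t={vol.time_h} h")
        if vol.counts.shape != region_mask.shape:
            raise ValueError("region mask and counts are on different grids")
        _, total_mCi = calibrate_counts(vol)
        if scale_factor is not None:
            total_mCi *= scale_factor
        fraction = vol.counts[region_mask].sum() / total_counts
        times.append(vol.time_h)
        acts.append(fraction * total_mCi)
    order = np.argsort(times)
    times = np.asarray(times)[order]
    acts = np.asarray(acts)[order]
    if times[0] != 0:
        raise ValueError("series must include an EOI frame at t=0")
    return TimeActivityCurve(times, acts, region_label)


def cumulated_activity(
    tac: TimeActivityCurve,
    end_h: float = DEFAULT_INTEGRATION_END_H,
    tail: Literal["none", "physical_decay"] = "none",
    model: DecayModel = DecayModel(),
) -> float:
    """Cumulated activity A~ (mCi·h): trapezoidal integral of A(t) on [0, end_h].

    With ``tail="physical_decay"`` the analytic integral of pure physical
    decay beyond ``end_h``, A(end)/lambda, is added; the default matches a
    finite imaging window with no extrapolation.  Sample times beyond
    ``end_h`` are handled by linear interpolation at the window edge; a
    window extending past the last sample is an error under ``tail="none"``.
    """
    t, a = tac.times_h, tac.activities_mCi
    if end_h <= 0:
        raise ValueError(f"integration end must be > 0, got {end_h}")
    if end_h > t[-1]:
        if tail == "none":
            raise ValueError(
                f"window [0,{end_h}] extends past the last sample at {t[-1]} h; "
                "no extrapolation under tail='none'"
            )
        # integrate measured part, then pure decay from the last sample
        measured = float(np.trapezoid(a, t))
        a_last = a[-1]
        lam = model.lambda_per_h
        bridge = (a_last / lam) * (1.0 - model.decay_factor(end_h - t[-1]))
        a_end = a_last * model.decay_factor(end_h - t[-1])
        return measured + bridge + a_end / lam
    a_end = float(np.interp(end_h, t, a))
    inside = t < end_h
    tt = np.append(t[inside], end_h)
    aa = np.append(a[inside], a_end)
    integral = float(np.trapezoid(aa, tt))
    if tail == "physical_decay":
        integral += a_end / model.lambda_per_h
    return integral


def absorbed_dose(
    cumulated_mCi_h: float,
    tumor_volume_mL: float,
    density_g_per_mL: float = TISSUE_DENSITY_G_PER_ML,
) -> float:
    """Local-deposition absorbed dose, D = 7.126 x A~ / m, in Gy.

    Mass is ``tumor_volume_mL x density`` (default 1 g/mL).
    """
    mass_g = tumor_volume_mL * density_g_per_mL
    if mass_g <= 0:
        raise ValueError(f"tumor mass must be > 0, got {mass_g} g")
    if cumulated_mCi_h < 0:
        raise ValueError("cumulated activity must be nonnegative")
    return DOSE_CONSTANT_GY_G_PER_MCI_H * cumulated_mCi_h / mass_g


def dose_summary(
    cumulated_mCi_h: float,
    tumor_volume_mL: float,
    tvt_percent: float | None = None,
    dichotomy_Gy: float = 100.0,
) -> DoseSummary:
    """Assemble the per-patient dosimetry record, including the >=100 Gy flag
    used to dichotomize survival analyses."""
    dose = absorbed_dose(cumulated_mCi_h, tumor_volume_mL)
    return DoseSummary(
        cumulated_mCi_h=float(cumulated_mCi_h),
        tumor_mass_g=tumor_volume_mL * TISSUE_DENSITY_G_PER_ML,
        absorbed_dose_Gy=dose,
        ge_100Gy=bool(dose >= dichotomy_Gy),
        tvt_percent=tvt_percent,
    )


def organ_geometric_mean(anterior_counts: float, posterior_counts: float) -> float:
    """Conjugate-view planar count: I = sqrt(I1 x I2)."""
    if anterior_counts < 0 or posterior_counts < 0:
        raise ValueError("planar counts must be nonnegative")
    return math.sqrt(anterior_counts * posterior_counts)


def percent_injected_dose(organ_activity_mCi: float, administered_mCi: float) -> float:
    """Organ or sample activity as a percent of the administered activity."""
    if administered_mCi <= 0:
        raise ValueError(f"administered activity must be > 0, got {administered_mCi}")
    return 100.0 * organ_activity_mCi / administered_mCi


def organ_dose_local(
    cumulated_mCi_h: float,
    organ_mass_g: float,
    administered_mCi: float,
) -> tuple[float, float]:
    """Organ absorbed dose under the local-deposition approximation.

    Returns (dose_cGy, normalized_cGy_per_mCi).  This applies the same
    equilibrium dose constant as the tumor equation (100 x 7.126 = 712.6
    cGy·g/(mCi·h)); it ignores cross-organ photon dose and phantom geometry,
    so treat the output as a local-deposition approximation, not an
    OLINDA-grade organ dose.
    """
    if organ_mass_g <= 0:
        raise ValueError(f"organ mass must be > 0, got {organ_mass_g}")
    if administered_mCi <= 0:
        raise ValueError(f"administered activity must be > 0, got {administered_mCi}")
    dose_cGy = 100.0 * DOSE_CONSTANT_GY_G_PER_MCI_H * cumulated_mCi_h / organ_mass_g
    return dose_cGy, dose_cGy / administered_mCi


def urine_excretion(
    samples: Iterable[tuple[float, float, float, float]],
    administered_mCi: float,
    model: DecayModel = DecayModel(),
) -> list[dict]:
    """Per-interval urinary %ID from counted voided samples.

    Each sample is ``(t_start_h, t_end_h, counts, counts_per_mCi)``; the
    measured count rate is decay-corrected from the end of the collection
    interval back to administration (t=0) before conversion.  Intervals must
    be non-overlapping.  Returns per-interval dicts with cumulative %ID.
    """
    if administered_mCi <= 0:
        raise ValueError(f"administered activity must be > 0, got {administered_mCi}")
    ordered = sorted(samples, key=lambda s: s[0])
    rows: list[dict] = []
    cumulative = 0.0
    prev_end = -math.inf
    for t0, t1, counts, counts_per_mCi in ordered:
        if t1 <= t0:
            raise ValueError(f"interval ({t0},{t1}) is not forward in time")
        if t0 < prev_end:
            raise ValueError(f"interval ({t0},{t1}) overlaps the previous one")
        if counts < 0 or counts_per_mCi <= 0:
            raise ValueError("counts must be >= 0 and calibration > 0")
        prev_end = t1
        measured_mCi = counts / counts_per_mCi
        at_admin = decay_correct(measured_mCi, from_time_h=t1, to_time_h=0.0, model=model)
        pct = percent_injected_dose(at_admin, administered_mCi)
        cumulative += pct
        rows.append(
            {
                "t_start_h": t0,
                "t_end_h": t1,
                "pct_id": pct,
                "cumulative_pct_id": cumulative,
            }
        )
    return rows
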
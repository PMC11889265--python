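"""SPECT count quantification: calibration against a standard source,
fixed-threshold segmentation of the treated region, and coverage metrics.

The quantification chain mirrors routine clinical practice for single-photon
imaging of an intracranially infused radiopharmaceutical:

1. voxel counts are converted to activity using a sealed vial of known
   activity imaged alongside the patient (counts-to-mCi calibration);
2. optionally, the end-of-infusion (EOI) frame is rescaled so the total image
   activity equals the administered activity, and that same factor is shared
   by the later frames;
3. the treated region (volume of distribution, Vd) is the set of voxels at or
   above a fixed fraction of the maximum voxel value;
4. coverage is summarized as Vd, the overlap with the gross tumor volume
   (GTV), and the percent tumor volume treated, %TVT = TuV/GTV x 100.

Grids must be pre-registered: mask and activity volumes share shape and voxel
spacing, and no resampling is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fraction-of-maximum cut used to delineate the treated region.  40% of the
#: maximum voxel is the common nuclear-medicine convention for fixed-threshold
#: segmentation; always configurable and recorded in run manifests.
DEFAULT_THRESHOLD_FRACTION = 0.40


class CalibrationError(ValueError):
    """Raised when the standard source cannot be used for calibration."""


@dataclass(frozen=True)
class StandardSource:
    """Sealed vial of known activity imaged with the patient.

    ``known_activity_mCi`` must already be decay-corrected to the acquisition
    time of the frame it calibrates.
    """

    known_activity_mCi: float
    measured_counts: float

    def __post_init__(self) -> None:
        if self.known_activity_mCi <= 0:
            raise CalibrationError(
                f"standard source activity must be > 0, got {self.known_activity_mCi}"
            )
        if self.measured_counts <= 0:
            raise CalibrationError(
                f"standard source counts must be > 0, got {self.measured_counts}"
            )

    @property
    def mci_per_count(self) -> float:
        return self.known_activity_mCi / self.measured_counts


@dataclass
class ActivityVolume:
    """A single calibrated SPECT-like frame: 3D counts + geometry + timing."""

    counts: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    time_h: float
    calibration: StandardSource | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3D, got ndim={self.counts.ndim}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class TreatedRegion:
    """Fixed-threshold segmentation result with coverage metrics."""

    mask: np.ndarray
    threshold_fraction: float
    vd_mL: float
    gtv_mL: float
    tumor_overlap_mL: float
    tvt_percent: float


def calibrate_counts(volume: ActivityVolume) -> tuple[np.ndarray, float]:
    """Convert a counts volume to a per-voxel activity field (mCi).

    activity(v) = counts(v) x known_activity / measured_counts.

    Returns
    -------
    (activity_field, total_mCi)
    """
    if volume.calibration is None:
        raise CalibrationError("no standard source attached to this frame")
    activity = volume.counts * volume.calibration.mci_per_count
    return activity, float(activity.sum())


def whole_image_scale_correction(
    activity_field: np.ndarray,
    administered_mCi: float,
    apply: bool = True,
    factor: float | None = None,
) -> tuple[np.ndarray, float]:
    """Rescale the field so the total equals the administered activity.

    Intended for the EOI frame, where all administered activity is in the
    field of view; pass the returned ``factor`` back in for later frames so
    every time point shares the EOI correction.

    Returns ``(field, factor)``; with ``apply=False`` the field is returned
    unchanged and the factor is 1.0.
    """
    activity_field = np.asarray(activity_field, dtype=float)
    if administered_mCi <= 0:
        raise ValueError(f"administered activity must be > 0, got {administered_mCi}")
    if not apply:
        return activity_field, 1.0
    if factor is None:
        total = activity_field.sum()
        if total <= 0:
            raise ValueError("total image activity is 0; cannot scale to administered")
        factor = administered_mCi / total
    return activity_field * factor, float(factor)


def threshold_region(activity_field: np.ndarray, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION) -> np.ndarray:
    """Binary mask of voxels at or above ``threshold_fraction`` of the max.

    Ties exactly at the cut are included.  Raises on an all-zero field, which
    has no maximum to threshold against.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError(f"threshold_fraction must be in (0,1), got {threshold_fraction}")
    activity_field = np.asarray(activity_field, dtype=float)
    peak = activity_field.max()
    if peak <= 0:
        raise ValueError("activity field has no positive maximum; cannot threshold")
    return activity_field >= threshold_fraction * peak


def coverage_metrics(
    mask: np.ndarray,
    gtv_mask: np.ndarray,
    voxel_size_mm: Sequence[float],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> TreatedRegion:
    """Vd, GTV overlap and %TVT for a treated-region mask.

    Both masks must live on the same pre-registered grid; shape mismatch is a
    hard error (co-registration happens upstream of this package).
    """
    mask = np.asarray(mask, dtype=bool)
    gtv_mask = np.asarray(gtv_mask, dtype=bool)
    if mask.shape != gtv_mask.shape:
        raise ValueError(
            f"treated mask {mask.shape} and GTV mask {gtv_mask.shape} are on different grids"
        )
    voxel_mL = float(np.prod(tuple(voxel_size_mm))) / 1000.0
    if voxel_mL <= 0:
        raise ValueError("voxel volume must be positive")
    gtv_vox = int(gtv_mask.sum())
    if gtv_vox == 0:
        raise ValueError("GTV mask is empty; %TVT is undefined")
    vd_mL = float(mask.sum()) * voxel_mL
    overlap_mL = float((mask & gtv_mask).sum()) * voxel_mL
    gtv_mL = gtv_vox * voxel_mL
    return TreatedRegion(
        mask=mask,
        threshold_fraction=threshold_fraction,
        vd_mL=vd_mL,
        gtv_mL=gtv_mL,
        tumor_overlap_mL=overlap_mL,
        tvt_percent=100.0 * overlap_mL / gtv_mL,
    )


def quantify_frame(
    volume: ActivityVolume,
    gtv_mask: np.ndarray,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    scale_factor: float | None = None,
) -> tuple[np.ndarray, float, TreatedRegion]:
    """Calibrate one frame and segment it: the per-frame quantification step.

    ``scale_factor`` is the shared EOI whole-image correction (1.0 disables).
    Returns (activity_field_mCi, total_mCi, treated_region).
    """
    activity, _ = calibrate_counts(volume)
    if scale_factor is not None:
        activity = activity * scale_factor
    mask = threshold_region(activity, threshold_fraction)
    region = coverage_metrics(mask, gtv_mask, volume.voxel_size_mm, threshold_fraction)
    return activity, float(activity.sum()), region
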
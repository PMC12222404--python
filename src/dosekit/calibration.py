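"""Scanner and patient-specific count-to-activity calibration.

Two calibrations live here:

* the *phantom conversion factor* from a uniform cylindrical phantom of known
  volume and activity (counts/s per MBq/mL), estimated over a central ROI to
  avoid edge and partial-volume effects; and
* the *patient-relative* scale used by voxel dosimetry, which divides the net
  injected activity by the total counts inside the whole-liver (WL) mask.
  The patient-relative route is deliberately independent of acquisition time
  and scanner sensitivity, and avoids any mismatch between the geometry of a
  calibration source and the patient's anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .image import VolumetricImage

__all__ = [
    "PhantomSpec",
    "ConversionFactor",
    "CalibrationError",
    "phantom_conversion_factor",
    "patient_count_to_activity_scale",
]


class CalibrationError(ValueError):
    """Raised when a calibration input is degenerate (empty ROI, zero counts)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Uniform calibration phantom: volume (mL), activity (MBq), scan
    duration (s) and the fraction of the phantom volume kept as central ROI.

    Defaults mirror a 6200 mL cylinder holding 605.33 MBq of Y-90 chloride
    with the central 70% used for counting.  Decay between assay and scan is
    the caller's responsibility (apply it to ``activity`` beforehand).
    """

    volume_ml: float = 6200.0
    activity_mbq: float = 605.33
    acquisition_duration_s: float = 1.0
    roi_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.activity_mbq <= 0:
            raise ValueError("phantom volume and activity must be positive")
        if not 0 < self.roi_fraction <= 1:
            raise ValueError("roi_fraction must lie in (0, 1]")
        if self.acquisition_duration_s <= 0:
            raise ValueError("acquisition duration must be positive")

    @property
    def concentration_mbq_per_ml(self) -> float:
        return self.activity_mbq / self.volume_ml


@dataclass(frozen=True)
class ConversionFactor:
    """Counts/s per MBq/mL, with the phantom it came from as provenance."""

    value: float
    phantom: PhantomSpec

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("conversion factor must be positive")

    def to_dict(self) -> dict:
        return {"value_cps_per_mbq_ml": self.value, "phantom": asdict(self.phantom)}


def central_roi(phantom_mask: np.ndarray, roi_fraction: float) -> np.ndarray:
    """Erode the phantom mask isotropically until its volume is at most
    ``roi_fraction`` of the original (ties broken toward the smaller ROI)."""
    mask = np.asarray(phantom_mask, bool)
    full = int(mask.sum())
    if full == 0:
        raise CalibrationError("phantom mask is empty")
    target = roi_fraction * full
    roi = mask
    structure = ndimage.generate_binary_structure(3, 3)
    while roi.sum() > target:
        eroded = ndimage.binary_erosion(roi, structure)
        if not eroded.any():
            raise CalibrationError(
                "central ROI vanished before reaching the requested fraction")
        roi = eroded
    return roi


def phantom_conversion_factor(phantom_image: VolumetricImage,
                              spec: PhantomSpec,
                              phantom_mask: np.ndarray) -> ConversionFactor:
    """Conversion factor CF = count rate in the central ROI divided by the
    activity contained in the ROI volume (uniform concentration assumed).

    CF = (sum counts in ROI / duration) / (concentration * V_ROI), with the
    ROI realised by isotropic erosion to ``spec.roi_fraction`` of the phantom
    mask.  Invariant to a joint doubling of activity and counts, and — on a
    noiseless uniform phantom — to the ROI fraction itself.
    """
    roi = central_roi(phantom_mask, spec.roi_fraction)
    counts = float(np.asarray(phantom_image.values)[roi].sum())
    if counts <= 0:
        raise CalibrationError("no counts inside the central ROI")
    roi_volume_ml = roi.sum() * phantom_image.voxel_volume_mm3 / 1000.0
    count_rate = counts / spec.acquisition_duration_s
    activity_in_roi = spec.concentration_mbq_per_ml * roi_volume_ml
    return ConversionFactor(count_rate / activity_in_roi, spec)


def patient_count_to_activity_scale(spect_counts: VolumetricImage,
                                    wl_mask: np.ndarray,
                                    injected_activity_gbq: float) -> float:
    """MBq per count: net injected activity divided by total WL counts.

    Per-voxel activity is then ``A(v) = scale * counts(v)``; by construction
    the activity summed over the whole liver equals the injected activity,
    and the scale is invariant to any global rescaling of the count map.
    """
    if injected_activity_gbq <= 0:
        raise CalibrationError("injected activity must be positive")
    wl = np.asarray(wl_mask, bool)
    total = float(np.asarray(spect_counts.values)[wl].sum())
    if total <= 0:
        raise CalibrationError("whole-liver mask contains no counts")
    return injected_activity_gbq * 1000.0 / total
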
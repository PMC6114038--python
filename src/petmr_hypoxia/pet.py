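"""PET SUV quantification, muscle-reference normalization, and
threshold-based hypoxic-subvolume segmentation.

The hypoxic subvolume (HSV) of a gross tumour volume (GTV) is defined
relative to a normal-tissue (NT) reference sphere in the contralateral
sternocleidomastoid muscle: a GTV voxel is hypoxic when its FMISO uptake is
at least ``factor`` (default 1.4) times the NT SUVmean of the same session.
Because the threshold is relative, segmentation is invariant to rescaling
the image, so it works identically on raw SUV and NT-normalized inputs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .images import RoiMask, SuvImage

#: Relative FMISO threshold defining hypoxia: uptake >= 1.4 x NT SUVmean.
DEFAULT_THRESHOLD_FACTOR = 1.4


def compute_suv(activity_kbq_ml: np.ndarray, injected_dose_mbq: float,
                body_weight_kg: float, geometry, tracer: str = "FMISO") -> SuvImage:
    """Standardized uptake value from an activity-concentration volume.

    SUV = activity [Bq/ml] / (dose [Bq] / weight [g]), assuming tissue
    density 1 g/ml. Decay correction is assumed applied upstream.
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive (MBq)")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive (kg)")
    activity = np.asarray(activity_kbq_ml, dtype=float)
    if np.any(activity < 0):
        raise ValueError("activity concentrations must be non-negative")
    suv = (activity * 1e3) / (injected_dose_mbq * 1e6 / (body_weight_kg * 1e3))
    return SuvImage(values=suv, tracer=tracer, geometry=geometry, units_state="suv")


def reference_uptake(suv: SuvImage, nt_mask: RoiMask) -> float:
    """Arithmetic SUVmean over the normal-tissue reference sphere."""
    suv.geometry.require_compatible(nt_mask.geometry, "SUV image vs NT mask")
    if nt_mask.is_empty:
        raise ValueError("NT reference mask is empty")
    return float(np.mean(suv.values[nt_mask.mask]))


def normalize_to_nt(suv: SuvImage, nt_mask: RoiMask) -> SuvImage:
    """Divide every voxel by the NT SUVmean; the NT mean of the output is 1."""
    if suv.units_state != "suv":
        raise ValueError("image is already NT-normalized")
    ref = reference_uptake(suv, nt_mask)
    if ref == 0:
        raise ValueError("NT reference uptake is zero; cannot normalize")
    return suv.with_values(suv.values / ref, units_state="nt_normalized")


def segment_hsv(fmiso: SuvImage, gtv: RoiMask, nt_mask: RoiMask,
                factor: float = DEFAULT_THRESHOLD_FACTOR,
                inclusive: bool = True) -> RoiMask:
    """Hypoxic subvolume: GTV voxels with uptake >= factor x NT SUVmean.

    Computed independently per timepoint from that session's FMISO image.
    The comparison is inclusive by default; an empty GTV yields an empty
    HSV with a warning.
    """
    if factor <= 0:
        raise ValueError("threshold factor must be positive")
    fmiso.geometry.require_compatible(gtv.geometry, "FMISO image vs GTV mask")
    if gtv.is_empty:
        warnings.warn(f"GTV {gtv.label!r} is empty; HSV is empty", stacklevel=2)
        hsv = np.zeros(gtv.geometry.shape, dtype=bool)
    else:
        threshold = factor * reference_uptake(fmiso, nt_mask)
        if inclusive:
            hsv = gtv.mask & (fmiso.values >= threshold)
        else:
            hsv = gtv.mask & (fmiso.values > threshold)
    label = "HSV-" + gtv.label.split("-", 1)[1] if gtv.label.startswith("GTV-") else "HSV"
    return RoiMask(mask=hsv, label=label, geometry=gtv.geometry, week=gtv.week)


def complement_subvolume(gtv: RoiMask, hsv: RoiMask) -> RoiMask:
    """Non-hypoxic complement within the GTV: nonHSV = GTV and not HSV."""
    gtv.geometry.require_compatible(hsv.geometry, "GTV vs HSV masks")
    if np.any(hsv.mask & ~gtv.mask):
        raise ValueError("HSV is not a subset of the GTV")
    label = "non" + hsv.label if hsv.label.startswith("HSV") else "nonHSV"
    return RoiMask(mask=gtv.mask & ~hsv.mask, label=label,
                   geometry=gtv.geometry, week=gtv.week)
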
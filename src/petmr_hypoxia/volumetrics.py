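"""Per-ROI statistics (mean, STD, volume) and longitudinal volume dynamics.

Volume is geometric (voxel count times voxel volume, reported in ml);
means and standard deviations are value-based and NaN-aware, so failed
relaxometry fits are excluded from the statistics but not from the volume.
Standard deviations are sample (n-1) throughout, matching conventional
"mean +/- STD" cohort reporting; a single-voxel ROI reports std 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import RoiMask

log = logging.getLogger(__name__)

#: Fixed column order of the tidy per-ROI statistics table.
STATS_COLUMNS = ["patient", "week", "structure", "metric",
                 "mean", "std", "n_voxels", "n_excluded", "volume_ml"]


@dataclass
class RoiStats:
    patient: str
    week: int
    structure: str
    metric: str
    mean: float
    std: float
    n_voxels: int
    n_excluded: int
    volume_ml: float

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in STATS_COLUMNS}


def mask_volume_ml(mask: RoiMask) -> float:
    """Geometric ROI volume in ml."""
    return mask.volume_ml()


def roi_stats(image: np.ndarray, mask: RoiMask, metric: str,
              patient: str = "", week: int | None = None) -> RoiStats:
    """Mean/STD of an image over a mask, plus the mask's geometric volume.

    Non-finite voxels (e.g. invalid T2* fits) are excluded from mean/std
    and counted in ``n_excluded``; empty or all-invalid masks report NaN
    statistics with n = 0. The volume always counts every mask voxel.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.geometry.shape:
        raise ValueError(
            f"image shape {image.shape} != mask grid {mask.geometry.shape}")
    values = image[mask.mask]
    finite = values[np.isfinite(values)]
    n_excluded = int(values.size - finite.size)
    if n_excluded:
        log.info("%s/%s week %s: %d invalid voxels excluded from statistics",
                 mask.label, metric, mask.week, n_excluded)
    if finite.size == 0:
        mean, std = np.nan, np.nan
    elif finite.size == 1:
        mean, std = float(finite[0]), 0.0
    else:
        mean, std = float(np.mean(finite)), float(np.std(finite, ddof=1))
    return RoiStats(
        patient=patient, week=mask.week if week is None else week,
        structure=mask.label, metric=metric, mean=mean, std=std,
        n_voxels=int(finite.size), n_excluded=n_excluded,
        volume_ml=mask.volume_ml())


def percent_change(v_start: float, v_end: float) -> float:
    """Signed percent change 100 * (end - start) / start; full precision."""
    if v_start == 0:
        log.warning("percent change undefined for zero baseline volume")
        return float("nan")
    return 100.0 * (v_end - v_start) / v_start


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (reporting convention)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def stats_table(rows: list[RoiStats]) -> pd.DataFrame:
    """Tidy long table of per-ROI statistics with the fixed column order."""
    return pd.DataFrame([r.as_row() for r in rows], columns=STATS_COLUMNS)


def build_cohort_table(per_patient: list[pd.DataFrame] | pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-patient tables and summarize each (week, structure, metric).

    Returns ``(long_table, summary)`` where the summary carries the group
    mean and sample STD of the patient-level means and volumes per cell;
    patients missing a cell are simply absent from it (their count is in
    ``n_patients``). One-patient cells report STD 0.
    """
    if isinstance(per_patient, pd.DataFrame):
        long = per_patient.copy()
    else:
        if len(per_patient) < 1:
            raise ValueError("need at least one patient table")
        long = pd.concat(per_patient, ignore_index=True)

    def agg(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        return pd.Series({
            "n_patients": n,
            "mean": group["mean"].mean(),
            "std": group["mean"].std(ddof=1) if n > 1 else 0.0,
            "volume_ml_mean": group["volume_ml"].mean(),
            "volume_ml_std": group["volume_ml"].std(ddof=1) if n > 1 else 0.0,
        })

    summary = (long.groupby(["week", "structure", "metric"], sort=True)
               .apply(agg, include_groups=False).reset_index())
    n_total = long["patient"].nunique()
    incomplete = summary[summary["n_patients"] < n_total]
    if len(incomplete):
        log.info("%d summary cells are missing patients (cohort n=%d)",
                 len(incomplete), n_total)
    return long, summary
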
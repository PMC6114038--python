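"""End-to-end per-patient analysis and the file-based pipeline driver.

Per session: estimate the MR noise level from the background, fit the T2*
map with noise-floor echo censoring, segment the hypoxic subvolumes of
tumour and nodes from the FMISO image at 1.4x the normal-tissue SUVmean,
form the complementary non-hypoxic subvolumes, and tabulate mean/STD and
volume of every metric in every structure. The cohort layer stacks the
per-patient tables, summarizes each (week, structure, metric) cell and
computes the regression endpoints (tracer-to-muscle ratios vs mean T2*).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig
from .geometry import GridGeometry
from .images import MultiEchoSeries, RoiMask, SuvImage
from .pet import complement_subvolume, reference_uptake, segment_hsv
from .phantom import PatientStudy
from .relaxometry import T2StarMap, compute_t2star_map, estimate_noise_level
from .stats import correlation_endpoints, suv_max
from .volumetrics import RoiStats, build_cohort_table, roi_stats, stats_table

log = logging.getLogger(__name__)

#: Structures tabulated at every session, in reporting order.
REPORTED_STRUCTURES = ("NT", "GTV-T", "GTV-LN", "HSV-T", "nonHSV-T",
                      "HSV-LN", "nonHSV-LN")


@dataclass
class SessionResult:
    """Derived images and masks for one patient-week."""

    week: int
    noise_level: float
    nt_reference: float           # FMISO SUVmean in NT
    threshold: float              # absolute HSV threshold this session
    t2star: T2StarMap
    masks: dict[str, RoiMask]     # includes HSV/nonHSV
    rows: list[RoiStats] = field(default_factory=list)


@dataclass
class StudyResult:
    patient: str
    sessions: dict[int, SessionResult]
    table: pd.DataFrame           # tidy per-ROI statistics
    endpoints: pd.DataFrame       # per-week regression endpoint values


def analyze_session(week: int, patient: str, series: MultiEchoSeries,
                    fmiso: SuvImage, masks: dict[str, RoiMask],
                    fdg: SuvImage | None = None,
                    threshold_factor: float = 1.4,
                    noise_floor_multiplier: float = 5.0) -> SessionResult:
    """Run every derivation stage for one imaging session."""
    for name, img_geom in (("FMISO", fmiso.geometry),) + (
            (("FDG", fdg.geometry),) if fdg is not None else ()):
        series.geometry.require_compatible(img_geom, f"MRI series vs {name} image")
    for label, m in masks.items():
        series.geometry.require_compatible(m.geometry, f"MRI series vs mask {label}")

    noise = estimate_noise_level(series, masks["background"])
    t2map = compute_t2star_map(series, noise, multiplier=noise_floor_multiplier)

    nt = masks["NT"]
    nt_ref = reference_uptake(fmiso, nt)
    threshold = threshold_factor * nt_ref
    log.info("%s week %d: NT FMISO SUVmean=%.4f, HSV threshold=%.4f "
             "(factor %.2f), MR noise level=%.4f",
             patient, week, nt_ref, threshold, threshold_factor, noise)

    derived = dict(masks)
    for structure in ("T", "LN"):
        gtv = masks[f"GTV-{structure}"]
        hsv = segment_hsv(fmiso, gtv, nt, factor=threshold_factor)
        derived[f"HSV-{structure}"] = hsv
        derived[f"nonHSV-{structure}"] = complement_subvolume(gtv, hsv)
        log.info("%s week %d: %s has %d voxels hypoxic of %d",
                 patient, week, gtv.label, hsv.n_voxels, gtv.n_voxels)

    rows = []
    for structure in REPORTED_STRUCTURES:
        mask = derived[structure]
        rows.append(roi_stats(t2map.t2star, mask, "T2*", patient, week))
        rows.append(roi_stats(fmiso.values, mask, "FMISO-SUV", patient, week))
        if fdg is not None:
            rows.append(roi_stats(fdg.values, mask, "FDG-SUV", patient, week))
    return SessionResult(week=week, noise_level=noise, nt_reference=nt_ref,
                         threshold=threshold, t2star=t2map, masks=derived,
                         rows=rows)


def _endpoint_rows(session: SessionResult, fmiso: SuvImage,
                   fdg: SuvImage | None, patient: str) -> list[dict]:
    """Per-structure SUVmax/NT-SUVmean ratios and mean T2* for regression."""
    rows = []
    nt = session.masks["NT"]
    fdg_nt = reference_uptake(fdg, nt) if fdg is not None else np.nan
    for structure in ("GTV-T", "GTV-LN"):
        gtv = session.masks[structure]
        t2_row = next(r for r in session.rows
                      if r.structure == structure and r.metric == "T2*")
        rows.append({
            "patient": patient, "week": session.week, "structure": structure,
            "fmiso_ratio": (suv_max(fmiso, gtv) / session.nt_reference
                            if not gtv.is_empty else np.nan),
            "fdg_ratio": (suv_max(fdg, gtv) / fdg_nt
                          if fdg is not None and not gtv.is_empty else np.nan),
            "t2star_mean": t2_row.mean,
        })
    return rows


def analyze_study(study: PatientStudy,
                  threshold_factor: float | None = None,
                  noise_floor_multiplier: float = 5.0) -> StudyResult:
    """Analyze every available session of one patient."""
    factor = study.threshold_factor if threshold_factor is None else threshold_factor
    sessions: dict[int, SessionResult] = {}
    all_rows: list[RoiStats] = []
    endpoint_rows: list[dict] = []
    for week in study.weeks:
        if week not in study.series or week not in study.fmiso:
            warnings.warn(f"{study.patient_id}: week {week} inputs missing; skipped",
                          stacklevel=2)
            continue
        fdg = study.fdg.get(week)
        sess = analyze_session(week, study.patient_id, study.series[week],
                               study.fmiso[week], study.masks[week], fdg,
                               threshold_factor=factor,
                               noise_floor_multiplier=noise_floor_multiplier)
        sessions[week] = sess
        all_rows.extend(sess.rows)
        endpoint_rows.extend(_endpoint_rows(sess, study.fmiso[week], fdg,
                                            study.patient_id))
    return StudyResult(patient=study.patient_id, sessions=sessions,
                       table=stats_table(all_rows),
                       endpoints=pd.DataFrame(endpoint_rows))


def analyze_cohort(studies: list[PatientStudy], **kwargs) -> dict:
    """Per-patient analysis, cohort summary and regression endpoints.

    Returns a dict with ``results`` (per-patient StudyResult), ``table``
    (stacked tidy statistics), ``summary`` (group mean/STD per cell) and
    ``regressions`` (R² rows per week and structure).
    """
    results = [analyze_study(s, **kwargs) for s in studies]
    long, summary = build_cohort_table([r.table for r in results])
    endpoints = pd.concat([r.endpoints for r in results], ignore_index=True)
    weeks = sorted(endpoints["week"].unique())
    regressions = pd.concat([correlation_endpoints(endpoints, w) for w in weeks],
                            ignore_index=True)
    return {"results": results, "table": long, "summary": summary,
            "endpoints": endpoints, "regressions": regressions}


# ---------------------------------------------------------------------------
# file-based driver

def _load_study(config: RunConfig) -> PatientStudy:
    series, fmiso, fdg, masks = {}, {}, {}, {}
    weeks = []
    for week, tp in sorted(config.timepoints.items()):
        required = {"series": tp.series, "echo_times": tp.echo_times,
                    "fmiso": tp.fmiso, "gtv_t": tp.gtv_t, "gtv_ln": tp.gtv_ln,
                    "nt": tp.nt, "background": tp.background}
        missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
        if missing:
            warnings.warn(f"week {week}: missing inputs {missing}; timepoint skipped",
                          stacklevel=2)
            continue
        data, geom = io.read_volume(tp.series)
        if data.ndim != 4:
            raise io.VolumeFormatError(f"multi-echo series must be 4-D: {tp.series}")
        te = io.read_echo_times(tp.echo_times)
        series[week] = MultiEchoSeries(signal=np.asarray(data, dtype=float),
                                       echo_times=te, geometry=geom)
        fm_data, fm_geom = io.read_volume(tp.fmiso)
        fmiso[week] = SuvImage(values=fm_data, tracer="FMISO", geometry=fm_geom)
        if tp.fdg and Path(tp.fdg).exists():
            fd_data, fd_geom = io.read_volume(tp.fdg)
            fdg[week] = SuvImage(values=fd_data, tracer="FDG", geometry=fd_geom)
        masks[week] = {
            "GTV-T": io.read_mask(tp.gtv_t, "GTV-T", week),
            "GTV-LN": io.read_mask(tp.gtv_ln, "GTV-LN", week),
            "NT": io.read_mask(tp.nt, "NT", week),
            "background": io.read_mask(tp.background, "background", week),
        }
        weeks.append(week)
    if not weeks:
        raise ValueError(f"no usable timepoints for patient {config.patient}")
    return PatientStudy(patient_id=config.patient, weeks=tuple(weeks),
                        series=series, fmiso=fmiso, fdg=fdg, masks=masks,
                        fmiso_dose_mbq=float("nan"), fdg_dose_mbq=float("nan"),
                        body_weight_kg=float("nan"),
                        threshold_factor=config.threshold_factor)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full per-patient pipeline from files; returns the output dir.

    Writes, per session: the T2*/S0/validity maps and HSV/nonHSV masks as
    NIfTI; plus a tidy statistics CSV, the endpoint CSV, and a JSON log of
    every noise level, NT reference and absolute threshold.
    """
    out = Path(config.output_dir) / config.patient
    out.mkdir(parents=True, exist_ok=True)
    study = _load_study(config)
    result = analyze_study(study, threshold_factor=config.threshold_factor,
                           noise_floor_multiplier=config.noise_floor_multiplier)
    run_log: dict = {"patient": config.patient,
                     "threshold_factor": config.threshold_factor,
                     "noise_floor_multiplier": config.noise_floor_multiplier,
                     "seed": config.seed, "sessions": {}}
    for week, sess in result.sessions.items():
        geom = sess.t2star.geometry
        io.write_volume(sess.t2star.t2star, geom, out / f"week{week}_t2star.nii.gz")
        io.write_volume(sess.t2star.s0, geom, out / f"week{week}_s0.nii.gz")
        io.write_volume(sess.t2star.n_echoes_used.astype(np.int16), geom,
                        out / f"week{week}_n_echoes.nii.gz", dtype=np.int16)
        for label in ("HSV-T", "nonHSV-T", "HSV-LN", "nonHSV-LN"):
            io.write_mask(sess.masks[label],
                          out / f"week{week}_{label.replace('*', '')}.nii.gz")
        run_log["sessions"][str(week)] = {
            "noise_level": sess.noise_level,
            "nt_fmiso_suvmean": sess.nt_reference,
            "hsv_threshold_abs": sess.threshold,
            "hsv_t_voxels": sess.masks["HSV-T"].n_voxels,
            "hsv_ln_voxels": sess.masks["HSV-LN"].n_voxels,
        }
    result.table.to_csv(out / "roi_stats.csv", index=False, float_format="%.6g")
    result.endpoints.to_csv(out / "endpoints.csv", index=False, float_format="%.6g")
    io.write_json(run_log, out / "run_log.json")
    return out
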
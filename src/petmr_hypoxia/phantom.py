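"""Synthetic longitudinal head-and-neck study with known ground truth.

The digital phantom stands in for a clinical cohort imaged at weeks 0, 2
and 5 of radiochemotherapy. Each patient is a set of nested spheres on a
shared voxel grid: a body region of normal tissue containing a shrinking
primary tumour (GTV-T) with a resolving hypoxic core, a shrinking nodal
volume (GTV-LN) with its own core, and a normal-tissue (NT) reference
sphere in muscle. Air outside the body has zero MR signal and zero tracer
uptake, which gives downstream noise estimation a genuine background.

Signal models
-------------
* MRI: per-voxel mono-exponential decay S(TE) = S0 exp(-TE/T2*) with
  Rician magnitude noise (independent Gaussian perturbations of two
  orthogonal channels, magnitude taken), so background voxels carry a
  Rayleigh noise floor exactly as in magnitude images.
* PET: designed uptake plus zero-mean Gaussian noise on the SUV scale,
  clipped at zero. Count statistics are upstream of reconstructed SUV
  images and are not modelled.

Default dimensions track the reported cohort scale: GTV-T 37 -> 24 -> 16 ml,
GTV-LN 16 -> 14 -> 7 ml, hypoxic cores 4 -> 1 -> 0 ml (tumour) and
2.1 -> 0.8 -> 0 ml (nodes) across weeks 0/2/5, tumour T2* ~18 ms against a
hypoxic 15 ms and muscle 21 ms, and an FMISO hypoxic-to-muscle uptake ratio
of 2.0, comfortably above the 1.4 segmentation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GridGeometry
from .images import MultiEchoSeries, RoiMask, SuvImage
from .relaxometry import default_echo_times

WEEKS = (0, 2, 5)


def _radius_for_ml(volume_ml: float) -> float:
    """Radius (mm) of a sphere with the given volume in ml."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic patient.

    Lengths are mm, times ms, uptakes SUV, dose MBq, weight kg. Radii are
    per-week tuples aligned with ``weeks`` and must be non-increasing
    (lesions shrink under treatment); a zero radius means the structure has
    resolved.
    """

    grid: GridGeometry = field(
        default_factory=lambda: GridGeometry.isotropic((64, 64, 48), (2.0, 2.0, 3.0)))
    weeks: tuple[int, ...] = WEEKS
    # geometry (world mm)
    body_center: tuple[float, float, float] = (64.0, 64.0, 72.0)
    body_radius: float = 60.0
    tumour_center: tuple[float, float, float] = (38.0, 45.0, 72.0)
    tumour_radii: tuple[float, ...] = tuple(_radius_for_ml(v) for v in (37.0, 24.0, 16.0))
    ln_center: tuple[float, float, float] = (38.0, 95.0, 72.0)
    ln_radii: tuple[float, ...] = tuple(_radius_for_ml(v) for v in (16.0, 14.0, 7.0))
    hypoxic_radii: tuple[float, ...] = tuple(_radius_for_ml(v) for v in (4.0, 1.0)) + (0.0,)
    ln_hypoxic_radii: tuple[float, ...] = tuple(_radius_for_ml(v) for v in (2.1, 0.8)) + (0.0,)
    nt_center: tuple[float, float, float] = (95.0, 40.0, 72.0)
    nt_radius: float = 10.0
    # MRI
    background_t2star: float = 21.0   # normal tissue / muscle, ms
    tumour_t2star: float = 18.0
    hypoxic_t2star: float = 15.0
    s0_level: float = 1000.0
    echo_times: np.ndarray = field(default_factory=default_echo_times)
    mri_noise_sigma: float = 10.0
    # PET (SUV units)
    nt_uptake: float = 1.0
    tumour_uptake: float = 1.1
    hypoxic_uptake: float = 2.0
    fdg_nt_uptake: float = 1.5
    fdg_tumour_uptake: float = 6.1
    fdg_hypoxic_uptake: float = 12.1
    fdg_ln_uptake: float = 4.7
    fdg_ln_hypoxic_uptake: float = 10.2
    pet_noise_sigma: float = 0.05
    # metadata
    fmiso_dose_mbq: float = 280.0
    fdg_dose_mbq: float = 380.0
    body_weight_kg: float = 75.0
    threshold_factor: float = 1.4
    seed: int = 0

    def validate(self) -> None:
        n = len(self.weeks)
        for name in ("tumour_radii", "ln_radii", "hypoxic_radii", "ln_hypoxic_radii"):
            radii = getattr(self, name)
            if len(radii) != n:
                raise ValueError(f"{name} must have one radius per week")
            if any(r < 0 for r in radii):
                raise ValueError(f"{name} must be non-negative")
            if any(b > a + 1e-12 for a, b in zip(radii, radii[1:])):
                raise ValueError(f"{name} must be non-increasing across weeks")
        for rc, rt in zip(self.hypoxic_radii, self.tumour_radii):
            if rc > rt:
                raise ValueError("hypoxic core must lie inside the tumour sphere")
        for rc, rt in zip(self.ln_hypoxic_radii, self.ln_radii):
            if rc > rt:
                raise ValueError("nodal hypoxic core must lie inside the nodal sphere")
        if np.asarray(self.echo_times).size == 0:
            raise ValueError("echo_times must be non-empty")
        if min(self.background_t2star, self.tumour_t2star, self.hypoxic_t2star) <= 0:
            raise ValueError("all T2* values must be positive")
        if self.hypoxic_radii[0] > 0 and \
                self.hypoxic_uptake / self.nt_uptake <= self.threshold_factor:
            raise ValueError(
                "hypoxic/NT uptake ratio must exceed the threshold factor at week 0")


@dataclass
class GroundTruth:
    """Designed maps, masks and volumes per week, for validating recovery."""

    t2star: dict[int, np.ndarray]
    suv: dict[str, dict[int, np.ndarray]]        # tracer -> week -> map
    masks: dict[int, dict[str, RoiMask]]         # week -> label -> mask
    volumes_ml: dict[int, dict[str, float]]      # week -> label -> ml


@dataclass
class PatientStudy:
    """All simulated images and masks for one patient across the weeks."""

    patient_id: str
    weeks: tuple[int, ...]
    series: dict[int, MultiEchoSeries]
    fmiso: dict[int, SuvImage]
    fdg: dict[int, SuvImage]                     # baseline only by default
    masks: dict[int, dict[str, RoiMask]]         # GTV-T, GTV-LN, NT, background
    fmiso_dose_mbq: float
    fdg_dose_mbq: float
    body_weight_kg: float
    threshold_factor: float = 1.4


def sphere_mask(geometry: GridGeometry, center: tuple[float, float, float],
                radius: float, label: str = "sphere",
                week: int | None = None) -> RoiMask:
    """Voxels whose world-space centers lie within ``radius`` mm of ``center``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    x, y, z = geometry.voxel_centers_world()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    mask = d2 <= radius**2
    if not mask.any() and radius > 0:
        warnings.warn(
            f"sphere at {center} (r={radius} mm) contains no voxel centers; "
            "the center may lie outside the grid", stacklevel=2)
    return RoiMask(mask=mask, label=label, geometry=geometry, week=week)


def synthesize_multiecho(t2star_map: np.ndarray, s0_map: np.ndarray,
                         echo_times: np.ndarray, noise_sigma: float,
                         seed: int | np.random.Generator = 0,
                         geometry: GridGeometry | None = None,
                         rician: bool = True) -> MultiEchoSeries:
    """Multi-echo magnitude series from designed T2*/S0 maps.

    Noise is Rician by default: independent N(0, sigma) perturbations are
    added to the ideal signal and to an orthogonal zero channel, and the
    magnitude is taken, so background (S0 = 0) voxels carry a Rayleigh
    floor. ``rician=False`` adds plain Gaussian noise clipped at zero.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    echo_times = np.asarray(echo_times, dtype=float)
    if np.any(echo_times <= 0) or np.any(np.diff(echo_times) <= 0):
        raise ValueError("echo_times must be strictly increasing and positive")
    t2 = np.asarray(t2star_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    if t2.shape != s0.shape:
        raise ValueError("T2* and S0 maps must share a grid")
    if geometry is None:
        geometry = GridGeometry.isotropic(t2.shape)

    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-echo_times[None, None, None, :] / t2[..., None])
    ideal = s0[..., None] * np.where(np.isfinite(decay), decay, 0.0)
    ideal = np.where(s0[..., None] > 0, ideal, 0.0)

    if noise_sigma == 0:
        signal = ideal
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, ideal.shape)
        if rician:
            n2 = rng.normal(0.0, noise_sigma, ideal.shape)
            signal = np.sqrt((ideal + n1) ** 2 + n2**2)
        else:
            signal = np.clip(ideal + n1, 0.0, None)
    return MultiEchoSeries(signal=signal, echo_times=echo_times, geometry=geometry)


def synthesize_pet(uptake_map: np.ndarray, noise_sigma: float,
                   seed: int | np.random.Generator = 0,
                   geometry: GridGeometry | None = None,
                   tracer: str = "FMISO") -> SuvImage:
    """Designed SUV map plus zero-mean Gaussian noise, clipped at zero."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    uptake = np.asarray(uptake_map, dtype=float)
    if np.any(uptake < 0):
        raise ValueError("uptake map must be non-negative")
    if geometry is None:
        geometry = GridGeometry.isotropic(uptake.shape)
    if noise_sigma == 0:
        values = uptake.copy()
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = np.clip(uptake + rng.normal(0.0, noise_sigma, uptake.shape), 0.0, None)
    return SuvImage(values=values, tracer=tracer, geometry=geometry, units_state="suv")


def _paint(base: np.ndarray, mask: np.ndarray, value: float) -> None:
    base[mask] = value


def design_week(spec: PhantomSpec, week_index: int) -> tuple[
        np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict[str, RoiMask]]:
    """Designed (t2star, s0, fmiso_suv, fdg_suv, masks) for one week."""
    g = spec.grid
    week = spec.weeks[week_index]
    body = sphere_mask(g, spec.body_center, spec.body_radius, "body", week)
    def structure(center, radius, label):
        # radius 0 means the structure has resolved: no voxels, even if the
        # center coincides with a voxel center
        if radius <= 0:
            return RoiMask(mask=np.zeros(g.shape, bool), label=label,
                           geometry=g, week=week)
        return sphere_mask(g, center, radius, label, week)

    gtv_t = structure(spec.tumour_center, spec.tumour_radii[week_index], "GTV-T")
    gtv_ln = structure(spec.ln_center, spec.ln_radii[week_index], "GTV-LN")
    core_t = structure(spec.tumour_center, spec.hypoxic_radii[week_index],
                       "hypoxic-truth")
    core_ln = structure(spec.ln_center, spec.ln_hypoxic_radii[week_index],
                        "hypoxic-truth-LN")
    nt = sphere_mask(g, spec.nt_center, spec.nt_radius, "NT", week)
    background = RoiMask(mask=~body.mask, label="background", geometry=g, week=week)

    t2 = np.full(g.shape, np.nan)
    _paint(t2, body.mask, spec.background_t2star)
    _paint(t2, gtv_t.mask | gtv_ln.mask, spec.tumour_t2star)
    _paint(t2, core_t.mask | core_ln.mask, spec.hypoxic_t2star)
    s0 = np.where(body.mask, spec.s0_level, 0.0)

    fmiso = np.zeros(g.shape)
    _paint(fmiso, body.mask, spec.nt_uptake)
    _paint(fmiso, gtv_t.mask | gtv_ln.mask, spec.tumour_uptake)
    _paint(fmiso, core_t.mask, spec.hypoxic_uptake)
    _paint(fmiso, core_ln.mask, spec.hypoxic_uptake)

    fdg = np.zeros(g.shape)
    _paint(fdg, body.mask, spec.fdg_nt_uptake)
    _paint(fdg, gtv_t.mask, spec.fdg_tumour_uptake)
    _paint(fdg, gtv_ln.mask, spec.fdg_ln_uptake)
    _paint(fdg, core_t.mask, spec.fdg_hypoxic_uptake)
    _paint(fdg, core_ln.mask, spec.fdg_ln_hypoxic_uptake)

    masks = {"GTV-T": gtv_t, "GTV-LN": gtv_ln, "NT": nt, "background": background,
             "hypoxic-truth-T": core_t, "hypoxic-truth-LN": core_ln}
    return t2, s0, fmiso, fdg, masks


def generate_study(spec: PhantomSpec,
                   patient_id: str = "phantom-01") -> tuple[PatientStudy, GroundTruth]:
    """Simulate one patient's full longitudinal study plus its ground truth.

    FDG is acquired at baseline (first week) only, matching the study
    schedule; FMISO and the multi-echo MRI are simulated at every week.
    Identical specs (including seed) give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.grid
    series: dict[int, MultiEchoSeries] = {}
    fmiso_imgs: dict[int, SuvImage] = {}
    fdg_imgs: dict[int, SuvImage] = {}
    study_masks: dict[int, dict[str, RoiMask]] = {}
    gt_t2, gt_suv_fmiso, gt_suv_fdg = {}, {}, {}
    gt_masks, gt_volumes = {}, {}

    for wi, week in enumerate(spec.weeks):
        t2, s0, fmiso, fdg, masks = design_week(spec, wi)
        series[week] = synthesize_multiecho(
            t2, s0, spec.echo_times, spec.mri_noise_sigma, rng, geometry=g)
        fmiso_imgs[week] = synthesize_pet(
            fmiso, spec.pet_noise_sigma, rng, geometry=g, tracer="FMISO")
        if wi == 0:
            fdg_imgs[week] = synthesize_pet(
                fdg, spec.pet_noise_sigma, rng, geometry=g, tracer="FDG")
        study_masks[week] = {k: masks[k] for k in ("GTV-T", "GTV-LN", "NT", "background")}
        gt_t2[week] = t2
        gt_suv_fmiso[week] = fmiso
        gt_suv_fdg[week] = fdg
        gt_masks[week] = masks
        gt_volumes[week] = {label: m.volume_ml() for label, m in masks.items()}

    study = PatientStudy(
        patient_id=patient_id, weeks=spec.weeks, series=series,
        fmiso=fmiso_imgs, fdg=fdg_imgs, masks=study_masks,
        fmiso_dose_mbq=spec.fmiso_dose_mbq, fdg_dose_mbq=spec.fdg_dose_mbq,
        body_weight_kg=spec.body_weight_kg, threshold_factor=spec.threshold_factor)
    truth = GroundTruth(t2star=gt_t2, suv={"FMISO": gt_suv_fmiso, "FDG": gt_suv_fdg},
                        masks=gt_masks, volumes_ml=gt_volumes)
    return study, truth


def cohort_specs(n_patients: int = 10, seed: int = 0,
                 base: PhantomSpec | None = None) -> list[PhantomSpec]:
    """Per-patient phantom specs with realistic between-patient variation.

    A latent hypoxia-severity factor z ~ N(0,1) per patient couples the
    endpoints the study correlates: more severe hypoxia means higher FMISO
    core uptake, higher FDG core uptake and shorter core T2*. Structure
    sizes get independent multiplicative jitter shared across weeks, so
    shrinkage trajectories are preserved patient by patient.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = []
    for p in range(n_patients):
        z = float(rng.normal())
        eps = float(rng.normal())
        size_t = float(np.exp(rng.normal(0.0, 0.15)))
        size_ln = float(np.exp(rng.normal(0.0, 0.15)))
        size_core = min(float(np.exp(rng.normal(0.0, 0.20))), size_t / 0.6)
        hyp_uptake = max(2.0 + 0.25 * z, 1.6 * base.nt_uptake)
        spec = replace(
            base,
            tumour_radii=tuple(r * size_t for r in base.tumour_radii),
            ln_radii=tuple(r * size_ln for r in base.ln_radii),
            hypoxic_radii=tuple(min(rc * size_core, rt * size_t * 0.95)
                                for rc, rt in zip(base.hypoxic_radii, base.tumour_radii)),
            ln_hypoxic_radii=tuple(min(rc * size_core, rt * size_ln * 0.95)
                                   for rc, rt in zip(base.ln_hypoxic_radii, base.ln_radii)),
            hypoxic_uptake=hyp_uptake,
            fdg_hypoxic_uptake=max(base.fdg_hypoxic_uptake + 3.0 * (0.8 * z + 0.6 * eps),
                                   base.fdg_tumour_uptake),
            hypoxic_t2star=float(np.clip(base.hypoxic_t2star - 1.5 * z, 8.0, 25.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
    return specs


def generate_cohort(n_patients: int = 10, seed: int = 0,
                    base: PhantomSpec | None = None
                    ) -> list[tuple[PatientStudy, GroundTruth]]:
    """Simulate a seeded cohort of phantom patients."""
    return [generate_study(spec, patient_id=f"phantom-{p + 1:02d}")
            for p, spec in enumerate(cohort_specs(n_patients, seed, base))]
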
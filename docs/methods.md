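# Methods

## Scope and data model

The pipeline analyses co-registered 3-D volumes on a shared voxel grid:
a 4-D multi-echo magnitude MRI series with its echo-time vector, FMISO and
FDG PET volumes in SUV units, and binary ROI masks (primary tumour GTV-T,
nodal GTV-LN, normal-tissue reference NT, background air), repeated at
treatment weeks 0, 2 and 5. Grid compatibility (same shape, affine equal
to 1e-5 relative) is enforced everywhere two volumes meet; **no resampling
or registration is performed** — images are assumed co-registered
upstream, and silently resampling quantitative maps would corrupt them, so
incompatible grids are a hard error. Voxel indices are 0-based, world
coordinates come only from the affine, lengths are mm and volumes ml.

## T2* relaxometry

Signal model: mono-exponential decay S(TE) = S₀·exp(−TE/T2\*) per voxel.
The default protocol is 12 echoes at TEₖ = 4.83 + k·2.55 ms (k = 0…11,
last echo 32.88 ms — the arithmetic sequence is used throughout).

**Noise level.** Magnitude images have Rician noise; in signal-free
background the magnitude is Rayleigh with mean σ√(π/2). The channel noise
σ is estimated as (mean background magnitude over all echoes)/√(π/2). A
background mask whose mean signal decays across echoes (first-echo mean
> 1.5× last-echo mean) triggers a tissue-contamination warning.

**Echo censoring.** To avoid the Rician noise floor biasing the fit, the
fit keeps only the leading contiguous run of echoes with signal ≥ 5σ
(multiplier configurable): once one echo falls below the floor, it and all
later echoes are dropped. A per-echo censoring variant is available but
the contiguous-prefix rule is the default, since the noise floor is
reached monotonically in an exponential decay and the prefix rule keeps
the TE spacing regular. At least 3 surviving echoes are required (2 points
always fit exactly, leaving no residual information); voxels below that
are invalid (NaN).

**Fit.** The default estimator is weighted log-linear least squares:
OLS of ln S on TE with weights S², the delta-method variance stabilization
for log-transformed data. It is exact (≤1e-6 relative) on noise-free data
for any T2* in [5, 100] ms and is deterministic and fast (fully vectorized
over voxels). An optional nonlinear least-squares refinement of the
exponential model, always initialized at the log-linear solution, reduces
the residual noise bias slightly at low SNR. Estimates outside
(0, 500] ms are physically implausible for neck tissue at 3 T and are
marked invalid (the cap is logged).

**Accuracy.** SNR is referenced to the *first echo* — the measured image
magnitude over σ — since the TE = 0 amplitude S₀ is never observed.
At first-echo SNR 30 the median absolute relative T2* error is ≤ 3.8% for
T2* ∈ {15, 18, 21} ms (see `analysis/02_t2star_recovery.py`), dominated by
noise propagation with a small positive bias from the Rician floor and
the keep-if-above-floor selection.

## PET quantification and HSV segmentation

SUV = activity[Bq/ml] / (dose[Bq]/weight[g]) with tissue density 1 g/ml;
decay correction is assumed applied in reconstruction. The NT reference is
the arithmetic SUVmean over a sphere contoured in the contralateral
sternocleidomastoid muscle; FDG images can be normalized to it (NT mean of
the output is exactly 1), and the normalization state is tracked so it
cannot be applied twice.

The hypoxic subvolume is HSV = {voxel ∈ GTV : SUV_FMISO ≥ 1.4 ×
SUVmean(NT)}, evaluated independently per timepoint from that session's
FMISO image. Choices made where the definition is underdetermined:

* the comparison is **inclusive** (≥), configurable;
* the HSV is **restricted to the GTV** (per-structure, giving HSV-T and
  HSV-LN) rather than free-standing PET blobs;
* because the threshold is relative, segmentation is invariant to any
  positive rescaling of the image, so raw SUV and NT-normalized inputs
  give identical subvolumes.

nonHSV = GTV \ HSV; the partition identities (disjoint, union = GTV,
volumes additive) hold exactly and are tested.

## ROI statistics and cohort tables

Per structure and week the pipeline reports mean ± sample STD (n−1) and
the geometric volume (voxel count × voxel volume / 1000 ml). Statistics
are NaN-aware: invalid T2* voxels are excluded from mean/STD (the excluded
count is reported and logged) but still count toward volume — volume is
geometry, statistics are values. Empty ROIs (e.g. resolved HSVs at week 5)
report NaN statistics with n = 0 and volume 0. Percent change is
100·(V_end − V_start)/V_start, kept at full precision internally and
rounded half-away-from-zero to integers only at the reporting layer.
Cohort tables are long/tidy CSV with a fixed column order; the summary
layer reports the group mean and STD of patient-level means per
(week, structure, metric) cell, with patients missing a timepoint simply
absent from that cell.

## Group statistics

Paired t-test: t = mean(d)/(std(d)/√n), df = n−1, two-sided p from the
t-distribution. Identical pairs give t = 0, p = 1; zero-variance nonzero
differences give a signed infinite t with p = 0 rather than an error.
Regression: OLS with R² = 1 − SSres/SStot (equal to the squared sample
correlation; constant y defines R² = 0) and the slope's two-sided t-test
p-value. The endpoints mirror the study design: per structure,
FMISO SUVmax(GTV)/SUVmean(NT) against mean T2*(GTV) at every week, and
against the FDG ratio at baseline only (FDG is acquired once). Tests are
two-sided at α = 0.05 with **no multiple-testing correction** — this
matches conventional small-cohort reporting and is a known limitation;
pairwise deletion handles missing patients.

## The digital phantom

The phantom emulates the study conditions at cohort scale. Geometry: a
spherical "body" of normal tissue in air; a primary-tumour sphere whose
volume shrinks 37 → 24 → 16 ml over weeks 0/2/5; a nodal sphere shrinking
16 → 14 → 7 ml; hypoxic cores of 4 → 1 → 0 ml (tumour) and
2.1 → 0.8 → 0 ml (nodes) — a radius of 0 means the structure has resolved
and contributes no voxels; an NT sphere of ~4 ml in "muscle". Default grid
64×64×48 at 2×2×3 mm, a deliberate compromise: coarse enough that a
3-week, 10-patient cohort simulates in seconds, fine enough that sphere
discretization errors stay within a voxel shell.

Tissue parameters: T2* 21 ms (normal tissue), 18 ms (tumour/node), 15 ms
(hypoxic core); S₀ = 1000 with Rician noise σ = 10 (first-echo SNR ≈ 76
at tumour T2*). FMISO uptake 1.0 (muscle) / 1.1 (tumour rim) / 2.0
(hypoxic core) SUV — the core-to-muscle ratio 2.0 clears the 1.4
threshold by design, so recovery is well-posed; FDG 1.5 / 6.1 / 12.1
(tumour) and 4.7 / 10.2 (nodes), matching the scale of reported subvolume
contrasts. PET noise is Gaussian on the SUV scale (σ = 0.05), clipped at
zero: count statistics live upstream of reconstructed SUV images and are
out of scope. MRI noise is Rician (magnitude of a complex Gaussian), which
is precisely why the noise-floor censoring exists; a pure-Gaussian option
is provided for unit tests.

Cohort generation draws, per patient, multiplicative lognormal size
factors (σ_log = 0.15–0.2, shared across weeks so every patient keeps a
shrinking trajectory) and a latent hypoxia-severity factor z ~ N(0,1) that
couples the correlated endpoints: higher z raises FMISO core uptake
(2.0 + 0.25z) and FDG core uptake, and shortens core T2* (15 − 1.5z ms).
This makes baseline FMISO-vs-FDG and FMISO-vs-T2* regressions
well-defined without asserting any particular clinical effect size.

**What the phantom does not model:** irregular lesion shapes, partial
volume at boundaries, air–tissue susceptibility gradients, perfusion
effects on T2*, intra-tumour uptake heterogeneity beyond the two-level
core/rim design, motion, and registration error. Passing tests therefore
demonstrate the correctness of the computational chain under the stated
models — not clinical performance on patient images.

## Numerical choices

* Grid compatibility tolerance 1e-5 relative on the affine.
* Volumes from |det| of the affine's 3×3 block (shear-safe).
* Weighted log-linear sums computed with masked vectorized accumulations;
  a voxel with a kept zero/negative signal is invalid rather than fitted.
* Sphere masks include a voxel iff its center's world distance to the
  sphere center is ≤ radius (radius 0 on a voxel center keeps exactly
  that voxel); an off-grid center yields an empty mask with a warning.
* NIfTI I/O via nibabel; values round-trip at float32, masks as uint8.
* All randomness flows through numpy Generators seeded from explicit
  integers; identical seeds give bit-identical volumes and byte-identical
  output tables.

## Problem sizes

The test suite exercises a compact phantom (40×40×30 at 2×2×3 mm) for
speed, the default-scale phantom for the cohort trend, a 64³ volume for
noise-free exactness, and ≥1200 voxels per condition for the noisy
recovery claims; `scripts/acceptance.py` uses the same sizes with a
10-patient cohort. These sizes are the package's own choice of study
conditions and are stated here so results are interpretable.
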
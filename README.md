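# petmr-hypoxia

Multiparametric PET/MR analysis of tumour hypoxia in head-and-neck
squamous cell carcinoma (HNSCC) under radiochemotherapy, built as a tested,
reusable pipeline and exercised end to end on a synthetic longitudinal
digital phantom with known ground truth.

Serial imaging studies of HNSCC ask whether the MRI relaxation time T2* —
shortened by paramagnetic deoxyhaemoglobin — can stand in for
FMISO-PET as a hypoxia marker during treatment. Answering that requires a
chain of quantitative steps, each of which this package implements and
tests:

* **T2\* relaxometry** — voxelwise mono-exponential fit
  S(TE) = S₀·exp(−TE/T2\*) to a 12-echo gradient-echo series
  (TEₖ = 4.83 + k·2.55 ms), with noise-floor censoring: echoes whose
  magnitude falls below 5× the channel noise level σ (estimated from the
  background via the Rayleigh mean E|n| = σ√(π/2)) are dropped from the
  fit to avoid the Rician noise bias.
* **PET quantification** — standardized uptake values
  SUV = activity / (dose/weight), normalization to the mean uptake of a
  normal-tissue (NT) reference sphere in the contralateral
  sternocleidomastoid muscle.
* **Hypoxic-subvolume segmentation** — HSV = {voxel ∈ GTV :
  SUV_FMISO ≥ 1.4 × SUVmean(NT)}, computed independently per timepoint,
  with the complementary non-hypoxic subvolume nonHSV = GTV \ HSV.
* **ROI statistics** — mean ± sample STD and geometric volume (ml) per
  structure (NT, GTV-T, GTV-LN, HSV/nonHSV) per week, longitudinal
  percent changes, and cohort summary tables.
* **Group statistics** — paired t-tests between subvolumes and OLS R²
  between the endpoints SUVmax(GTV)/SUVmean(NT) for FMISO/FDG and mean
  T2*(GTV).
* **Digital phantom** — a longitudinal synthetic cohort (weeks 0/2/5)
  of shrinking tumour and nodal spheres with resolving hypoxic cores,
  Rician MRI noise and Gaussian PET noise, providing ground truth for
  every stage.

## Layout

* `src/petmr_hypoxia/` — the library: `geometry`/`images`/`io` (grids,
  containers, NIfTI), `phantom`, `relaxometry`, `pet`, `volumetrics`,
  `stats`, `pipeline`, `cli`.
* `analysis/` — numbered drivers reproducing the study's analyses on the
  synthetic cohort; each writes tables under `results/`.
* `scripts/acceptance.py` — recomputes the headline numbers from scratch.

## Worked example

```python
from petmr_hypoxia import PhantomSpec, generate_study, analyze_study

study, truth = generate_study(PhantomSpec(seed=1))
result = analyze_study(study)
for week, sess in result.sessions.items():
    print(week, round(sess.masks["HSV-T"].volume_ml(), 3),
          round(truth.volumes_ml[week]["hypoxic-truth-T"], 3))
```

prints the measured vs designed hypoxic tumour subvolume (ml) per week:

```
0 3.912 3.912
2 1.032 1.032
5 0.0 0.0
```

— at the default PET noise (σ = 0.05 SUV) the 1.4×NT threshold recovers
the designed core exactly, and the hypoxic volume resolves by week 5.
Running the numbered drivers (`python analysis/04_cohort_tables.py`)
produces the cohort-mean volume dynamics; with the 10-patient cohort at
seed 20:

```
structure  week0_ml  week2_ml  week5_ml  pct_change_0_5
    GTV-T   49.8192   32.2752   21.4848             -57
   GTV-LN   17.3616   15.1800    7.6416             -56
    HSV-T    3.6048    0.9120    0.0000            -100
   HSV-LN    1.9128    0.7200    0.0000            -100
```

i.e. tumour volumes roughly halve over treatment while the hypoxic
subvolumes all but vanish — the reoxygenation pattern the pipeline is
designed to quantify.

The same stages are available as CLI subcommands
(`petmr-hypoxia simulate|fit-t2star|suv|segment-hsv|roi-stats|cohort-stats|run`).

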
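# Methods

## The prediction model

The package applies — never refits — a published logistic model for
pathological complete response (pCR) after neoadjuvant chemoradiotherapy in
locally advanced rectal cancer. The linear predictor is

```
lp = −6.18 − 0.95·cT + 0.53·cN − 3.01·S + 3.61·E,    P(pCR) = 1/(1+e^−lp)
```

with clinical T and N stage coded as ordinal integers (T2→2 … T4→4,
N0→0 … N2→2; a single coefficient per covariate rules out dummy coding) and
two first-order radiomic covariates computed inside the gross tumour volume
(GTV) of the staging T2-weighted image: skewness `S` after a
Laplacian-of-Gaussian (LoG) filter of kernel width σ = 0.485 mm and
histogram entropy `E` after σ = 0.344 mm. The per-coefficient standard
deviations (3.00, 0.36, 0.35, 1.17, 1.68) are carried as metadata only.
Classification uses the published threshold 0.267 with the boundary counted
as positive; this convention is fixed so confusion matrices are
reproducible, and is echoed into every report.

The original publication does not restate the feature-extraction internals
of the platform it used, so four conventions had to be decided here; all
are configurable (`FeatureConfig`) and recorded in every report:

- **Entropy discretisation**: 64 equal-width bins over the ROI min–max of
  the filtered response, log base 2. A fixed bin *number* (rather than a
  fixed width) makes entropy invariant to positive linear intensity
  scalings — the natural choice for arbitrary-unit MR intensities.
- **Skewness convention**: population moments, `m3/m2^1.5`, no bias
  correction. Zero variance raises an error rather than silently returning
  0.
- **Filter dimensionality**: in-plane 2-D by default (σ converted per axis
  via dx, dy only, slices independent). The source images are 2-D
  acquisitions with ~3 mm slices; a 0.34–0.49 mm σ along the slice axis
  would be far below one voxel and numerically meaningless. A full 3-D mode
  exists for sensitivity analysis.
- **Scale normalisation**: the response is σ²·∇²(G∗I) in physical
  coordinates. Both downstream features are invariant to any global factor,
  so this cannot change model output; it is fixed only so intermediate
  arrays are reproducible.

Numerical details of the filter: separable sampled-Gaussian kernels,
truncation at 4σ, reflect padding at edges; the second-derivative kernel is
DC-corrected to exact zero sum, so a constant image yields an exactly zero
response even at sub-voxel σ (plain sampling leaves a visible bias there —
σ = 0.344 mm on a 0.5 mm grid is σ ≈ 0.69 voxels). Sigmas below 0.1× the
finest spacing trigger an under-resolved warning, not an error. ROIs
smaller than 10 voxels are rejected: third moments and 64-bin histograms
are unstable below that.

No resampling and no intensity normalisation are applied before filtering
(none are described for the original pipeline); voxel spacing enters only
through the σ conversion. Volumes and masks are read from NIfTI/NRRD with
spacing taken from the header and intensities untouched; orientation
matrices beyond spacing are ignored because both features are
orientation-invariant.

## Validation statistics

- **AUC**: Mann–Whitney midrank form, `P(s⁺>s⁻) + ½P(s⁺=s⁻)`; the
  trapezoidal integral of the step ROC equals it identically (asserted to
  1e-12 in tests).
- **AUC CI**: DeLong placement-value variance by default (the original
  report does not name its method), normal quantiles, clipped to [0, 1]; a
  stratified 2000-rep percentile bootstrap is available and the two agree
  within 20% on the cohort sizes used here. The method is recorded in the
  report.
- **Threshold metrics**: positive call iff score ≥ threshold; accuracy,
  sensitivity, specificity, NPV, PPV with Clopper–Pearson exact intervals
  (conservative by construction; coverage is simulation-checked at the NPV
  denominator size, n = 34). Zero-denominator metrics are reported as
  undefined with a reason, never as NaN.
- **Youden threshold**: candidates are the observed score values; ties in
  J = sens + spec − 1 break toward the lowest threshold.
- **Kappa**: `(p_o − p_e)/(1 − p_e)` with the asymptotic-SE interval.
- **Cohort comparisons**: Pearson chi-square *without* continuity
  correction (this is what reproduces the published sex p-value of 0.56)
  and two-sided Mann–Whitney U with tie correction for continuous
  variables.
- **Subgroups** (scanner field strength 1.5 T vs 3 T): identical thresholds
  — the published cut-off and the *pooled* Youden cut-off — are applied in
  every subgroup; a single-class subgroup is flagged "AUC undefined", not
  fatal. Reports always list the published-threshold block first: under
  external-validation semantics the cut-off is part of the model under
  test.

**Confusion-matrix reconstruction.** Published performance tables give
metrics to 2 d.p. but not the matrices. With known margins (n, n_pos) the
space of integer matrices is tiny, so an exhaustive search returns the
matrix minimising the number of metrics whose rounding disagrees with the
printed column, erroring on ambiguity or poor fit (< 3 of 5 matched). On
the whole-cohort column this yields a unique matrix (TP=7, FN=3, FP=18,
TN=31) that reproduces sensitivity/NPV/PPV exactly; its accuracy (0.644)
and specificity (0.633) round to one step below the printed 0.65/0.64, and
its kappa is 0.208 vs the printed 0.22 — the printed column is not
simultaneously consistent with any integer matrix, which the tooling
surfaces rather than hides. The two field-strength columns match at most
2 of 5 metrics for any positive split and are therefore reported as not
self-consistent; no subgroup matrix is claimed.

## Synthetic data

The generator exists so the pipeline is testable end-to-end without
patient images; it makes no claim of MR realism (no coil bias, no Rician
noise, no anatomy), which is exactly why passing tests demonstrate
*pipeline* correctness — I/O, unit handling, filter maths, statistics —
and nothing about clinical performance.

- **Phantoms**: anisotropic grid (default 0.5 × 0.5 × 3 mm — typical
  in-plane pixel and slice thickness for staging rectal T2) holding an
  ellipsoidal ROI over smoothed-noise background. ROI texture is a
  smoothed unit-variance field pushed through the monotone map
  `u → sinh(λ + u) − sinh(λ)`, so λ = 0 gives a symmetric histogram and the
  sign of λ sets the skewness sign. Deterministic given the seed.
- **Cohorts**: cT drawn with probabilities (0.102, 0.576, 0.322), cN
  (0.424, 0.407, 0.169), field strength 32:27 for 1.5 T : 3 T — the
  published validation-cohort margins. Labels either `model-bernoulli`
  (pcr ~ Bernoulli(model score); used for parameter recovery) or
  `fixed-prevalence` (exactly n_pos positives, e.g. 10 of 59, drawn without
  replacement with probability proportional to the model score so the
  planted signal survives the conditioning). In the fast tabular mode the
  two features are sampled uniformly from S ∈ [−1.5, 1.5] and
  E ∈ [1, 5] bits — synthetic conventions (no feature distributions are
  published) chosen so predicted probabilities span roughly (0.01, 0.9).
  With uniform draws the mean predicted probability is ≈ 0.63 and the
  model separates Bernoulli labels with AUC ≈ 0.97; both exceed the
  clinical setting, which is why the 59-patient rehearsals use
  fixed-prevalence mode (prevalence 16.9%, moderate AUC) instead. In image
  mode each patient gets a phantom with per-patient texture parameters and
  the features (hence scores and labels) come from actual extraction, so
  the simulated table is exactly what the imaging pipeline re-extracts.
- **Seeding**: one global seed fans out through `SeedSequence(seed,
  spawn_key=(patient_index,))`, so cohorts are reproducible under
  reordering and any subset of patients can be regenerated independently.

**Parameter recovery** refits an unpenalised logistic regression
(statsmodels MLE) on `model-bernoulli` cohorts of n = 5000 and checks
whether each generating coefficient lies in its 95% Wald interval. Three
seeds are run and ≥ 4 of 5 covered per run is required; with five
simultaneous 95% intervals the all-five rate is ≈ 0.77, so an occasional
single miss is expected behaviour. n = 5000 keeps the binomial information
high enough that the intercept (true SE ≈ 0.37) is testable while the
three-run experiment completes in a few seconds.

## Problem sizes and reproducibility

Default experiment sizes: 59-patient image cohorts on 48 × 48 × 12 grids
(≈ 2300 ROI voxels per phantom), 5000-patient tabular cohorts for
refitting, 10⁵ for margin checks, 2000 bootstrap replicates. Every output
embeds the config echo, its SHA-256 hash and the package version; repeated
runs with the same seed produce identical feature tables byte-for-byte and
identical report numerics (the config echo differs only in output paths).

## Known limitations

- The feature-extraction conventions above are this package's decisions,
  not published facts; agreement with the original platform's numeric
  output cannot be verified without it.
- Any centring/scaling the original training applied to S and E before
  entering the model is unknown; raw features are assumed, and this is
  flagged in the report configuration echo.
- The DeLong/Clopper–Pearson/asymptotic-kappa interval choices are
  defensible defaults, not reconstructions of the original analysis.
- Phantom cohorts cannot validate the simulated feature *scales* against
  real tumours; they validate mechanics, invariances and statistics only.
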
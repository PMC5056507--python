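# Methods

This note documents the models, conventions and numerical choices behind
`spnradiomics`, in the order the pipeline applies them, and states what the
synthetic cohorts do and do not establish about real CT data.

## ROI handling

An ROI arrives as a binary raster aligned with a single 2-D slice in
Hounsfield units.  Before any feature is computed the ROI is *refined*:
only pixels whose **original** HU lies in the closed window [−50, 300]
are kept.  The window drops air (below −50 HU) and bone/calcification
(above 300 HU).  Two conventions here are deliberate readings of an
underspecified procedure:

* the bounds are inclusive — "below −50" and "beyond 300" are read as
  strict exclusion;
* the window is applied once, to the unfiltered HU values, and the refined
  mask is then fixed across all filter scales.  Applying the window to
  filtered values would make the ROI support depend on σ and couple the
  feature families in ways that are hard to reason about.

Refinement is idempotent and monotone in the window, and never mutates the
input mask.  Geometry reporting (area = pixel count × spacing product;
maximum diameter = largest pairwise distance between in-mask pixel
centres, computed on the convex hull) exists for reproducibility
book-keeping.

## The 150-feature dictionary

Per scale σ ∈ {0, 1.0, 1.5, 2.0, 2.5}: 10 histogram + 20 GLCM features;
5 × 30 = 150.  Names follow the grammar `his_mean_σ`, `his_SD_σ`,
`his_β_mean_σ`, `his_SD_β_σ`, `kurtosis_σ`, `skewness_σ`,
`contrast_α_σ`, `correlation_α_σ`, `entropy_α_σ`, `energy_α_σ`,
`homogeneity_α_σ` with β ∈ {50, 25, 10} and α ∈ {0, 45, 90, 135}.

**LoG filtering.**  The kernel is the sampled
LoG(x, y) = −(1/(πσ⁴))·[1 − (x²+y²)/(2σ²)]·exp(−(x²+y²)/(2σ²)),
truncated at radius ⌈4σ⌉ pixels and mean-subtracted so the weights sum to
exactly zero (a constant image filters to exactly zero).  σ is in pixels;
σ = 0 denotes the identity.  The whole image is filtered before masking so
that mask-edge discontinuities do not dominate the band-pass response;
image boundaries use reflection.  Filtering is linear, so any global HU
offset vanishes at σ > 0 and shifts only the σ = 0 means.

**Histogram statistics.**  Sample moments with divisor N; kurtosis is
non-excess (a Gaussian sample converges to 3); skewness is μ₃/σ³.  The
top-β subset contains the M = round(β·N) largest intensities (M ≥ 1),
taken after a descending sort, so ties at the cut are resolved
deterministically.  A constant ROI is degenerate: SD = 0 and
kurtosis/skewness are reported as 0 rather than NaN.

**Quantization and GLCM.**  In-mask filtered values are quantized to
Ng = 64 equal-width bins spanning their min–max (the maximum maps to
level Ng; a constant ROI maps to level 1).  Ng is configurable; 64 keeps
the 64×64 co-occurrence matrix well-populated for ROIs of a few hundred
pixels without washing out contrast.  The GLCM at offset δ = 1 counts only
pairs with **both** endpoints inside the refined mask, accumulates each
pair in both orders (symmetric matrix) and normalises to a probability
distribution, which is what the marginal-based correlation formula
requires.  Entropy uses log base 2 (scale only).  Homogeneity weights are
1/(1+(i−j)²) — the inverse of the contrast weight (i−j)², not the
inverse-absolute-difference variant.  A GLCM whose marginals are
degenerate (single occupied level) reports correlation 0.

## Screening

Each feature is tested for a benign/malignant shift with the two-sided
Mann–Whitney U test (normal approximation with tie correction; the U
reported is min(U₁, U₂)).  When the rank sums are perfectly balanced
(U = n₁n₂/2, e.g. identical samples) p = 1 is returned directly — the
continuity correction would otherwise report p slightly below 1 for a
configuration carrying no ordering evidence.  Discrimination is the rank
AUC, U₁/(n₀n₁) = P(score_mal > score_ben) + ½P(tie), oriented so larger
values predict malignancy.

**No multiple-testing correction is applied**: screening at raw p < 0.05
mirrors common radiomics practice and is deliberately permissive — its job
is dimension reduction before the penalised fit, not inference.  Per-family
error control is the LASSO's job.  This is the single most important
caveat when reading screening counts.

## Signature fitting

The LASSO-logistic fit minimises per-observation log-loss plus λ‖β‖₁ on
features standardised to zero mean and unit variance (penalty fairness
across scales; constant columns are left unpenalisable and never
selected).  The λ path is geometric with 20 points from λ_max — the
smallest penalty with an all-zero solution, max|Xᵀ(y−ȳ)|/n — down to
λ_max/100 (the small-sample default of the reference R implementation of
penalised GLMs).  λ is chosen at minimum cross-validated binomial
deviance over stratified 10-fold splits with a fixed seed; the 1-SE rule
is not used because the study design calls only for "chosen by
cross-validation".  Individual fits use liblinear with a fixed internal
seed, so the whole procedure is bit-reproducible.  Coefficients are
back-transformed to the original feature scale and the reported score is
the full linear predictor including the intercept (rank-equivalent to the
fitted probability).

The signature is fitted **only** on the primary cohort's screening
survivors; the validation cohort is scored with the frozen model.  The
test suite asserts this leak-freedom by refitting from the primary data
alone and comparing coefficients.

## Evaluation

* **ROC.**  AUC by rank statistic; variance by DeLong's structural
  components (V₁₀ per positive, V₀₁ per negative); 95% CI as the normal
  interval clipped to [0, 1].  The classification cutoff maximises the
  Youden index over thresholds of the form "score ≥ t" with t swept over
  observed scores, ties breaking toward the lower threshold; cutoffs are
  optimised per cohort per group (a config switch reuses the primary
  cutoff on validation instead).
* **Paired DeLong.**  Covariance of the structural components of the two
  score sets on the same subjects; two-sided normal p.  Degenerate
  variance (identical or rank-identical scores) returns p = 1.  The
  implementation agrees with pROC's `roc.test(..., method="delong",
  paired=TRUE)` to 1e-7 (pinned in the test suite through Rscript).  Note
  that at n ≲ 30 the asymptotic p and an exact sign-flip permutation p of
  the same studentized statistic can differ by a few hundredths; this is a
  property of the normal reference, not an implementation artifact.
* **NRI.**  Two-category NRI at each signature's own best cutoff, events =
  malignant, "up" = reclassified into the malignant-predicted class.  The
  event and non-event components and their exact sum are returned together
  with the full movement table for audit.
* **ICC.**  ICC(A,1): two-way mixed effects, absolute agreement, single
  measures, from the standard mean-squares decomposition (agrees with
  pingouin's ICC(A,1) row to machine precision).  Absolute agreement
  penalises systematic offsets between readings.  Zero between-subject
  variance makes the coefficient undefined and is flagged as 0.  The form
  is configurable in the sense that the other McGraw–Wong forms can be
  derived from the same mean squares; A,1 is the default because a single
  reader's absolute reproducibility is what matters for feature stability.

## Synthetic cohorts

The generator emulates the study design, not CT physics:

* **Base texture.**  Inside an ellipse with randomised axes (8–16 px,
  ~0.7 mm/px) the nodule is a stationary Gaussian random field: smoothed
  white noise rescaled to a subject-level SD and correlation length, on a
  lung-like background (−820 ± 12 HU).  Class separation is encoded as
  (SD, correlation length): benign 18 HU / 2.0 px, malignant 26 HU /
  1.4 px, with lognormal between-subject spread (0.35 and 0.25 log-SD).
  The spread makes the classes overlap, so single-seed signature AUCs land
  in roughly 0.70–0.88 — imperfect discrimination comparable to published
  patient-level radiomics performance — rather than saturating at 1.
* **Acquisition operators**, applied to the same base image per subject
  (paired design):
  * group 2 (contrast): +45 HU global offset plus a multiplicative
    low-frequency confound field (amplitude 0.4, correlation 6 px) that is
    independent of the class — enhancement adds apparent heterogeneity
    unrelated to biology;
  * groups 3–4 (5 mm slices): Gaussian partial-volume blur with
    σ = 0.4·(thickness/1.25 − 1) px, i.e. 1.2 px at 5 mm and exactly 0 at
    1.25 mm;
  * group 4 (lung kernel): unsharp-mask boost (gain 0.8, radius 1 px) and
    additive band-pass noise (12 HU SD, difference-of-Gaussians band
    0.5–1.5 px) — high spatial frequencies and noise preserved.
  All strengths live in one `DegradationParams` block; none are measured
  scanner quantities.  With every strength at 0 the four groups are
  byte-identical, which pins the operators in tests.
* **Determinism.**  Every random draw descends from
  (cohort seed, cohort label, subject index, operator tag) through
  `SeedSequence`, so cohorts are reproducible at subject granularity and
  the contrast/kernel noise is independent of the base texture.

**What passing tests show — and do not show.**  On these cohorts the full
pipeline recovers the expected ordering: the clean reference acquisition
yields the best validation AUC, and each degradation costs performance.
That demonstrates the pipeline's statistical machinery end to end
(screening → sparse fit → paired comparison) under a known ground truth.
It does **not** calibrate the size of acquisition effects on real CT:
the generator has no anatomy, no scanner noise spectrum, no beam
hardening, no 3-D partial-volume geometry, and its effect sizes are
design choices.  Conclusions about real nodules still require patient
data.

## Problem sizes

Default cohorts are 30 benign + 90 malignant subjects per cohort (the
1:3 class ratio of consecutive-enrolment SPN series), two cohorts per
study run, 64×64 px images.  The stochastic study-level checks average
20 independent cohort seeds; oracle-equivalence checks use ≥100 random
small inputs; null-calibration checks use 500–2000 replicates.

## Known limitations

* 2-D single-slice only; no wavelet/shape/size feature families.
* Screening is uncorrected for multiplicity by design (see above).
* The DeLong CI/p are asymptotic; at very small n a permutation or
  bootstrap interval is preferable.
* The NRI is the two-category variant at data-driven cutoffs; it inherits
  the instability of cutoff optimisation and is reported with its movement
  table so that the raw counts are always visible.
* `fit_lasso` refits the path once per fold per λ without warm starts;
  for the default problem sizes this costs seconds, but for thousands of
  subjects a coordinate-descent path solver would be the right tool.
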
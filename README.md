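# spnradiomics

Radiomics texture signatures for solitary pulmonary nodules (SPNs), and how
CT acquisition conditions change their diagnostic value.

A solitary pulmonary nodule is a rounded lung opacity up to 3 cm on CT;
deciding whether it is benign or malignant from imaging alone is hard, and
quantitative texture analysis ("radiomics") of the nodule's region of
interest is one way to support that decision.  The catch is that the same
nodule looks different depending on how the CT was acquired and
reconstructed — with or without intravenous contrast, with thin (1.25 mm)
or thick (5 mm) slices, with a smooth *standard* or a sharp, noisy *lung*
convolution kernel.  This package implements the full analysis needed to
quantify that effect, end to end:

1. **Feature extraction** — 150 named texture features per (image, ROI)
   pair: for each Laplacian-of-Gaussian filter scale
   σ ∈ {0, 1.0, 1.5, 2.0, 2.5} (σ = 0 meaning no filtering),

   * 10 gray-level histogram statistics of the in-ROI filtered intensities
     X(1..N): mean (1/N)ΣX(i), SD (divisor N), the mean and SD of the top
     β ∈ {50%, 25%, 10%} of the histogram, kurtosis μ₄/σ⁴ and skewness
     μ₃/σ³;
   * 5 gray-level co-occurrence matrix (GLCM) statistics at offset δ = 1 in
     each direction α ∈ {0°, 45°, 90°, 135°}: contrast ΣΣ(i−j)²P(i,j),
     correlation ΣΣ(i−μₓ)(j−μ_y)P/(σₓσ_y), entropy −ΣΣP·log₂P, energy
     ΣΣP², homogeneity ΣΣP/(1+(i−j)²).

   The ROI is first refined to pixels with attenuation in [−50, 300] HU,
   removing air and calcification.

2. **Screening** — per-feature Mann–Whitney U test (benign vs malignant)
   and rank AUC, with the significant / AUC > 0.75 banding.

3. **Signature** — LASSO-penalised logistic regression on the screening
   survivors of a *primary* cohort (penalty at minimum cross-validated
   deviance, stratified 10-fold), giving a sparse radiomics score
   `intercept + Σ βⱼ·featureⱼ`; larger scores mean higher malignancy
   probability.  The fitted signature is applied unchanged to an
   independent *validation* cohort.

4. **Evaluation and comparison** — ROC analysis with DeLong-variance CIs
   and Youden-index cutoffs; the paired DeLong test for correlated AUCs;
   the two-category net reclassification improvement
   NRI = [P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)];
   and ICC(A,1) for repeat-measurement reproducibility.

5. **Synthetic cohorts** — no patient images ship with the package, so a
   seeded generator builds benign/malignant nodules as Gaussian random
   fields (malignant = higher HU variance, finer correlation length) and
   observes each subject under all four acquisition groups via explicit
   degradation operators (contrast offset + multiplicative confound;
   partial-volume blur; unsharp lung-kernel boost + band-pass noise).
   Everything downstream is exercised on these cohorts.

## Worked example

`examples/05_compare_groups.py` runs the whole study (30 benign + 90
malignant subjects per cohort, seed 1):

```
Diagnostic performance of the radiomics signature per group:
 group     cohort   AUC  CI95_low  CI95_high   SEN   SPE  Accuracy  cutoff
     1    primary 0.882     0.817      0.948 0.744 0.833     0.767   1.044
     1 validation 0.739     0.634      0.843 0.667 0.733     0.683   1.549
     2    primary 0.853     0.777      0.929 0.700 0.867     0.742   1.009
     2 validation 0.812     0.720      0.904 0.633 0.900     0.700   1.439
     3    primary 0.874     0.798      0.949 0.944 0.667     0.875   0.220
     3 validation 0.702     0.591      0.813 0.567 0.800     0.625   1.781
     4    primary 0.811     0.725      0.897 0.789 0.667     0.758   0.688
     4 validation 0.706     0.597      0.815 0.533 0.800     0.600   1.324
```

Each row is one acquisition group in one cohort: the signature's AUC with
its DeLong 95% CI, and sensitivity/specificity/accuracy at the
Youden-optimal score cutoff.  On any single seed the group ranking is
noisy; averaged over seeds the reference acquisition (group 1:
non-contrast + 1.25 mm + standard kernel) has the highest validation AUC,
with contrast enhancement, thick slices and the lung kernel each costing
discrimination — the package's tests pin exactly that ordering over 20
seeds.  The script also prints the three pre-registered paired comparisons
(1 vs 2, 1 vs 3, 3 vs 4) with DeLong p-values and NRI components.

The other examples are single-capability walk-throughs: cohort simulation
(01), feature extraction (02), screening (03), signature fitting (04) and
ICC reproducibility (06).  A thin CLI mirrors the pipeline for shell use:

```sh
spnrad simulate --n-benign 30 --n-malignant 90 --seed 1 --outdir data/
spnrad extract data/manifest_primary.csv --out features.csv
spnrad all --seed 1 --outdir report/
```

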
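"""Extract the 150-feature texture vector from one nodule slice.

The dictionary is 5 LoG scales x (10 histogram + 5 GLCM stats x 4
directions).  Scale 0 is the unfiltered image; larger sigma emphasises
coarser texture.
"""

from spnradiomics import CohortSpec, extract_all, generate_nodule, refine_roi

spec = CohortSpec(n_benign=1, n_malignant=1, seed=7)
image, mask = generate_nodule("malignant", 1, spec, subject_seed=0)

# the ROI is restricted to the [-50, 300] HU window (drops air/calcification)
refined = refine_roi(image, mask)
print(f"ROI pixels: {mask.n_pixels} drawn, {refined.n_pixels} after HU window")

features = extract_all(image, refined)
print(f"{len(features)} features extracted")
for name in (
    "his_mean_0", "his_SD_0", "his_10_mean_0", "kurtosis_0", "skewness_0",
    "contrast_0_1.0", "correlation_0_1.0", "entropy_0_1.0", "energy_0_1.0",
    "homogeneity_0_1.0",
):
    print(f"  {name:20s} {features[name]:10.4f}")
print("his_* are first-order statistics of in-ROI HU (top-beta percentile "
      "restricted where tagged); the GLCM statistics quantify spatial "
      "gray-level co-occurrence at offset 1 in the named direction, after "
      "LoG filtering at the trailing sigma.")
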
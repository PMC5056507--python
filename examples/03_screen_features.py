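"""Univariate screening of all features on a small primary cohort.

Each feature is tested for a benign/malignant shift (Mann-Whitney U,
two-sided) and scored by rank AUC; the study's feature map highlights
significant features with AUC > 0.75.
"""

from spnradiomics import CohortSpec, screen, simulate_cohort
from spnradiomics.pipeline import extract_cohort_features
from spnradiomics.features import feature_names

cohort = simulate_cohort(CohortSpec(n_benign=12, n_malignant=24, seed=3))
table = extract_cohort_features(cohort)

for gid in (1, 2, 3, 4):
    sub = table[table["group"] == gid]
    report = screen(sub[feature_names()], (sub["class"] == "malignant").to_numpy())
    n_sig = int(report["significant"].sum())
    n_good = int(report["good_performer"].sum())
    print(f"group {gid}: {n_sig:3d}/150 significant (p<0.05), "
          f"{n_good:3d} with AUC > 0.75")

print("More features survive screening on the clean reference acquisition "
      "(group 1) than on contrast-enhanced, thick-slice or lung-kernel "
      "images, where the texture signal is confounded or blurred away.")
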
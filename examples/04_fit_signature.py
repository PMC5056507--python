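"""Fit the LASSO-logistic radiomics signature on a primary cohort.

Screening survivors enter an L1-penalised logistic regression; the penalty
is chosen at minimum cross-validated deviance, so most coefficients shrink
to exactly zero and the few survivors form the signature.  The radiomics
score of a subject is the resulting linear predictor.
"""

import numpy as np

from spnradiomics import CohortSpec, fit_lasso, radiomics_score, screen, simulate_cohort
from spnradiomics.features import feature_names
from spnradiomics.pipeline import extract_cohort_features

cohort = simulate_cohort(CohortSpec(n_benign=20, n_malignant=40, seed=5))
table = extract_cohort_features(cohort)
sub = table[table["group"] == 1]
X = sub[feature_names()]
y = (sub["class"] == "malignant").to_numpy()

survivors = screen(X, y)
survivors = list(survivors.index[survivors["significant"]])
print(f"{len(survivors)} features passed screening")

model = fit_lasso(X[survivors], y, folds=10, seed=5)
print(f"lambda = {model.lam:.4f} (minimum CV deviance)")
print(f"{len(model.selected)} selected features:")
for name in model.selected:
    print(f"  {name:24s} coef {model.coefficients[name]:+.4f}")

scores = radiomics_score(model, X)
print(f"mean score benign {np.mean(scores[~y]):+.2f}, "
      f"malignant {np.mean(scores[y]):+.2f}")
print("A larger radiomics score means a higher fitted probability that the "
      "nodule is malignant.")
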
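"""Univariate feature screening: Mann-Whitney association and per-feature AUC.

Each of the 150 features is tested for a benign/malignant location shift
with the two-sided Mann-Whitney U test (the features are not assumed
normal) and scored for discrimination with the rank-based AUC, oriented so
that larger feature values predicting malignancy give AUC > 0.5.  Features
with p < 0.05 are "significant"; significant features with AUC above the
good-performance threshold (0.75) form the band highlighted in the study's
feature map.  No multiple-testing correction is applied — screening is
deliberately permissive, mirroring common radiomics practice; see
docs/methods.md for the caveat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mann_whitney", "feature_auc", "screen"]

ALPHA_DEFAULT = 0.05
GOOD_AUC = 0.75


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples.

    Returns ``(U, p)`` where U is the smaller of the two one-sided U
    statistics (min(U_x, U_y) convention).  p comes from the normal
    approximation with tie correction.  If every value in both samples is
    identical there is no ordering information and (n_x*n_y/2, 1.0) is
    returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return x.size * y.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    if u_min == x.size * y.size / 2.0:
        # perfectly balanced ranks carry no ordering evidence; the continuity
        # correction would otherwise report p slightly below 1
        return u_min, 1.0
    return u_min, float(min(res.pvalue, 1.0))


def feature_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score_malignant > score_benign) + 0.5 P(tie).

    ``labels`` is boolean/0-1 with 1 = malignant (the positive class).
    Equivalent to the normalised Mann-Whitney statistic U1/(n0*n1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = stats.rankdata(scores)
    u1 = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


def screen(
    features: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    good_auc: float = GOOD_AUC,
) -> pd.DataFrame:
    """Per-feature association and discrimination report.

    Parameters
    ----------
    features
        One row per subject, one column per feature.
    labels
        1/True = malignant.

    Returns a DataFrame indexed by feature name with columns ``U``, ``p``,
    ``auc``, ``significant`` (p < alpha), ``good_performer`` (significant
    and AUC > good_auc) and ``band`` (categorical map band).  Constant
    features are flagged with p = 1 and AUC = 0.5.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("screening needs at least 2 subjects per class")
    rows = []
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        u, p = mann_whitney(v[~labels], v[labels])
        auc = 0.5 if np.ptp(v) == 0 else feature_auc(v, labels)
        rows.append({"feature": name, "U": u, "p": p, "auc": auc})
    out = pd.DataFrame(rows).set_index("feature")
    out["significant"] = out["p"] < alpha
    out["good_performer"] = out["significant"] & (out["auc"] > good_auc)
    out["band"] = np.select(
        [~out["significant"], out["auc"] <= good_auc],
        ["not_significant", "significant"],
        default=f"significant_auc_gt_{good_auc}",
    )
    return out
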
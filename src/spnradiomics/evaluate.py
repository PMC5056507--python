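"""Discrimination/classification assessment and paired model comparison.

Implements the evaluation toolkit used to compare signatures across
acquisition groups:

* ROC analysis with the rank-based AUC, DeLong variance for the 95% CI,
  and the Youden-index best cutoff with sensitivity/specificity/accuracy;
* the paired DeLong test for the difference of two correlated AUCs
  measured on the same subjects;
* the two-category net reclassification improvement (NRI) with its event
  and non-event components and an auditable movement table;
* the intraclass correlation coefficient ICC(A,1) — two-way mixed effects,
  absolute agreement, single measures — for repeat-measurement
  reproducibility, with agreement called "good" above 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "NRIResult",
    "roc_analysis",
    "delong_paired",
    "nri",
    "icc_agreement",
]

ICC_GOOD = 0.75


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its per-subject structural components (V10, V01).

    V10[i] = P(score of positive i beats a random negative) and V01[j] the
    mirror quantity; their empirical variances give the DeLong variance of
    the AUC estimator.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC with DeLong-variance 95% CI, and classification at the best cutoff.

    The cutoff maximises the Youden index (sensitivity + specificity − 1)
    over thresholds of the form "predict malignant when score >= t", with t
    swept over the observed scores; ties on the index break toward the
    lower threshold.  The CI is the normal interval, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("ROC analysis requires both classes")
    auc, v10, v01 = _delong_components(scores, labels)
    se = np.sqrt(_auc_variance(v10, v01))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    thresholds = np.unique(scores)  # ascending; lowest threshold wins ties
    best = None
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & labels).sum() / m)
        spec = float((~pred & ~labels).sum() / n)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, cutoff, sens, spec = best
    acc = float(((scores >= cutoff) == labels).mean())
    return ROCResult(
        auc=auc, ci95=ci, cutoff=float(cutoff),
        sensitivity=sens, specificity=spec, accuracy=acc, youden=float(j),
    )


def delong_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Paired DeLong test for two score sets measured on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided p from the normal
    reference.  When the variance of the AUC difference is degenerate
    (e.g. identical or rank-identical scores) the difference carries no
    evidence and p = 1 is returned with z = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired DeLong needs aligned score/label vectors")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), min(p, 1.0)


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

@dataclass
class NRIResult:
    """Two-category NRI; 'up' means moving into the malignant-predicted class."""

    nri_events: float
    nri_nonevents: float
    total: float
    movement: dict[str, int] = field(default_factory=dict)


def nri(
    pred_old: np.ndarray, pred_new: np.ndarray, labels: np.ndarray
) -> NRIResult:
    """Net reclassification improvement from old to new predicted classes.

    nri_events     = P(up | event) − P(down | event)
    nri_non-events = P(down | non-event) − P(up | non-event)
    total          = nri_events + nri_nonevents   (exact identity)

    with events = malignant and "up" = reclassified from benign-predicted
    to malignant-predicted.
    """
    pred_old = np.asarray(pred_old).astype(bool)
    pred_new = np.asarray(pred_new).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if not (pred_old.shape == pred_new.shape == labels.shape):
        raise ValueError("NRI needs aligned prediction/label vectors")
    up = ~pred_old & pred_new
    down = pred_old & ~pred_new
    n_ev = int(labels.sum())
    n_ne = int((~labels).sum())
    if n_ev == 0 or n_ne == 0:
        raise ValueError("NRI requires both events and non-events")
    movement = {
        "events_up": int((up & labels).sum()),
        "events_down": int((down & labels).sum()),
        "events_unchanged": int((~up & ~down & labels).sum()),
        "nonevents_up": int((up & ~labels).sum()),
        "nonevents_down": int((down & ~labels).sum()),
        "nonevents_unchanged": int((~up & ~down & ~labels).sum()),
    }
    nri_ev = (movement["events_up"] - movement["events_down"]) / n_ev
    nri_ne = (movement["nonevents_down"] - movement["nonevents_up"]) / n_ne
    return NRIResult(
        nri_events=nri_ev,
        nri_nonevents=nri_ne,
        total=nri_ev + nri_ne,
        movement=movement,
    )


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc_agreement(m1: np.ndarray, m2: np.ndarray) -> float:
    """ICC(A,1): two-way mixed effects, absolute agreement, single measures.

    From the two-way ANOVA mean squares with n subjects and k = 2
    measurements,

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n),

    where MSR is the between-subject, MSC the between-measurement and MSE
    the residual mean square.  Absolute agreement penalises a systematic
    offset between the two measurements.  Zero between-subject variance
    makes the coefficient undefined; 0.0 is returned in that case.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("ICC needs two aligned 1-D measurement vectors")
    n = m1.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([m1, m2])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.allclose(row_means, grand) or denom <= 0:
        # no between-subject variance: agreement is undefined; flag as 0
        return 0.0
    return float((msr - mse) / denom)
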
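"""LASSO-penalised logistic signature fitting and the radiomics score.

The signature is fitted only on the primary cohort, on the features that
survived univariate screening.  Features are standardised to zero mean and
unit variance internally so the L1 penalty treats them symmetrically; the
model minimises

    (1/n) sum_i log(1 + exp(-y_i eta_i)) + lambda ||beta||_1,

with lambda chosen at minimum cross-validated binomial deviance over a
geometric lambda path (stratified K-fold, fixed seed).  Coefficients are
reported back on the original feature scale, and the radiomics score of a
subject is the linear predictor

    score = intercept + sum_j coef_j * feature_j,

so a larger score means a higher fitted probability of malignancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["SignatureModel", "fit_lasso", "radiomics_score"]


@dataclass
class SignatureModel:
    """A fitted sparse logistic signature (original-scale coefficients)."""

    feature_names: list[str]
    coefficients: dict[str, float]  # only the selected (non-zero) features
    intercept: float
    lam: float
    lambda_path: list[float]
    cv_deviance: list[float]  # mean CV deviance per lambda on the path
    nonzero_path: list[int]  # selected-feature count per lambda
    cv_folds: int
    seed: int
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return [f for f in self.feature_names if self.coefficients.get(f, 0.0) != 0.0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "selected": self.selected,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "lambda": self.lam,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "standardization": {"center": self.center, "scale": self.scale},
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # binomial deviance -2 sum log p(y|eta), numerically stable
    return float(2.0 * np.sum(np.logaddexp(0.0, -(2.0 * y - 1.0) * eta)))


def _fit_at_lambda(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimises C * sum log-loss + ||beta||_1, so C = 1/(n*lambda)
    C = 1.0 / (Xs.shape[0] * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=0,
    )
    clf.fit(Xs, y)
    return clf


def fit_lasso(
    features: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 1e-2,
    lam: float | None = None,
) -> SignatureModel:
    """Fit the L1 logistic signature with cross-validated penalty choice.

    Parameters
    ----------
    features
        Screened feature table (rows = primary-cohort subjects).
    labels
        1/True = malignant.
    folds, seed
        Stratified K-fold CV configuration; the same seed and data always
        reproduce the same model.
    n_lambdas, lambda_min_ratio
        Geometric path from the smallest lambda that zeroes every
        coefficient down to ``lambda_min_ratio`` times it.
    lam
        Fix the penalty instead of choosing it by cross-validation
        (duplication-invariance checks, sensitivity analyses).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    names = list(features.columns)
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} subjects per class for {folds}-fold "
            f"stratified CV (got {counts.min()})"
        )

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns stay at coefficient 0
    Xs = (X - center) / scale

    # lambda_max: smallest penalty with an all-zero solution
    p_bar = y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ (y - p_bar))) / n)
    path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    if lam is None:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(cv.split(Xs, y))
        cv_dev = np.zeros(n_lambdas)
        for train, test in splits:
            for k, l in enumerate(path):
                clf = _fit_at_lambda(Xs[train], y[train], l)
                eta = Xs[test] @ clf.coef_.ravel() + clf.intercept_[0]
                cv_dev[k] += _deviance(y[test], eta)
        cv_dev /= n
        lam = float(path[int(np.argmin(cv_dev))])
    else:
        lam = float(lam)
        cv_dev = np.full(n_lambdas, np.nan)
    final = _fit_at_lambda(Xs, y, lam)
    beta_std = final.coef_.ravel()
    beta = beta_std / scale
    intercept = float(final.intercept_[0] - np.sum(beta_std * center / scale))

    nonzero_path = [
        int(np.count_nonzero(_fit_at_lambda(Xs, y, l).coef_)) for l in path
    ]
    return SignatureModel(
        feature_names=names,
        coefficients={nm: float(b) for nm, b in zip(names, beta) if b != 0.0},
        intercept=intercept,
        lam=lam,
        lambda_path=[float(l) for l in path],
        cv_deviance=[float(d) for d in cv_dev],
        nonzero_path=nonzero_path,
        cv_folds=folds,
        seed=seed,
        center={nm: float(c) for nm, c in zip(names, center)},
        scale={nm: float(s) for nm, s in zip(names, scale)},
    )


def radiomics_score(model: SignatureModel, x: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
    """Linear radiomics score(s): intercept + sum(coef * feature).

    Accepts a single feature mapping (returns a float) or a DataFrame of
    subjects (returns an array).  A larger score indicates a higher
    probability of malignancy.  Missing selected features raise with the
    offending name.
    """
    if isinstance(x, dict):
        x = pd.Series(x)
    selected = model.selected
    if isinstance(x, pd.Series):
        missing = [f for f in selected if f not in x.index]
    else:
        missing = [f for f in selected if f not in x.columns]
    if missing:
        raise KeyError(f"missing selected feature(s): {', '.join(missing)}")
    if isinstance(x, pd.Series):
        return float(
            model.intercept
            + sum(model.coefficients[f] * float(x[f]) for f in selected)
        )
    out = np.full(len(x), model.intercept, dtype=float)
    for f in selected:
        out += model.coefficients[f] * x[f].to_numpy(dtype=float)
    return out
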
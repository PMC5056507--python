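"""End-to-end study pipeline: simulate → extract → screen → fit → evaluate → compare.

Mirrors the study design: a *primary* cohort drives feature screening and
LASSO signature fitting per acquisition group; the fitted signatures are
then applied, unchanged, to an independent *validation* cohort.  Per group
the pipeline reports the ROC analysis in both cohorts, and the three
pre-registered paired group comparisons (1 vs 2: contrast; 1 vs 3: slice
thickness; 3 vs 4: convolution kernel) with the DeLong test and the
two-category NRI at each signature's own best cutoff.

The validation cohort never influences screening, the penalty path or the
coefficients; :func:`run_study` fits everything from the primary cohort
before the validation features are even touched, and the test suite pins
this with a hash comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, screening, signature
from .features import NG_DEFAULT, SIGMAS, extract_all, feature_names
from .images import HU_WINDOW, refine_roi
from .synthetic import GROUPS, CohortSpec, SyntheticSubject, simulate_cohort

__all__ = [
    "PipelineConfig",
    "extract_cohort_features",
    "fit_group_signatures",
    "evaluate_groups",
    "compare_groups",
    "run_study",
    "StudyReport",
]

DEFAULT_COMPARISONS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (3, 4))


@dataclass
class PipelineConfig:
    """All knobs of the study pipeline in one place (defaults = study setup)."""

    seed: int = 0
    n_benign: int = 30
    n_malignant: int = 90
    ng: int = NG_DEFAULT
    sigmas: tuple[float, ...] = SIGMAS
    hu_window: tuple[float, float] = HU_WINDOW
    alpha: float = 0.05
    cv_folds: int = 10
    n_lambdas: int = 20
    comparisons: tuple[tuple[int, int], ...] = DEFAULT_COMPARISONS
    reuse_primary_cutoff: bool = False  # else re-optimise per cohort
    cohort_overrides: dict = field(default_factory=dict)

    def cohort_spec(self, label: str, seed_offset: int = 0) -> CohortSpec:
        return CohortSpec(
            n_benign=self.n_benign,
            n_malignant=self.n_malignant,
            cohort_label=label,
            seed=self.seed + seed_offset,
            **self.cohort_overrides,
        )


def extract_cohort_features(
    subjects: list[SyntheticSubject],
    ng: int = NG_DEFAULT,
    sigmas: tuple[float, ...] = SIGMAS,
    hu_window: tuple[float, float] = HU_WINDOW,
) -> pd.DataFrame:
    """Feature table: one row per (subject, group), 150 feature columns."""
    rows = []
    for s in subjects:
        for gid, image in s.images.items():
            refined = refine_roi(image, s.mask, *hu_window)
            feats = extract_all(image, refined, ng=ng, sigmas=sigmas)
            rows.append(
                {
                    "subject": s.subject_id,
                    "class": s.class_label,
                    "cohort": s.cohort,
                    "group": gid,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


def _split_group(table: pd.DataFrame, gid: int) -> tuple[pd.DataFrame, np.ndarray]:
    sub = table[table["group"] == gid].sort_values("subject").reset_index(drop=True)
    names = [c for c in sub.columns if c in set(feature_names())]
    return sub[names], (sub["class"] == "malignant").to_numpy()


def fit_group_signatures(
    primary_table: pd.DataFrame, config: PipelineConfig
) -> dict[int, dict]:
    """Screen and fit one LASSO signature per acquisition group (primary only)."""
    out: dict[int, dict] = {}
    for gid in GROUPS:
        X, y = _split_group(primary_table, gid)
        scr = screening.screen(X, y, alpha=config.alpha)
        survivors = list(scr.index[scr["significant"]])
        if not survivors:
            raise RuntimeError(
                f"group {gid}: no feature passed screening; cannot fit a signature"
            )
        model = signature.fit_lasso(
            X[survivors], y,
            folds=config.cv_folds, seed=config.seed, n_lambdas=config.n_lambdas,
        )
        out[gid] = {"screening": scr, "model": model}
    return out


def evaluate_groups(
    fitted: dict[int, dict],
    primary_table: pd.DataFrame,
    validation_table: pd.DataFrame,
    config: PipelineConfig,
) -> dict[int, dict]:
    """Score both cohorts per group and run the ROC analysis."""
    out: dict[int, dict] = {}
    for gid, bundle in fitted.items():
        model = bundle["model"]
        per_cohort = {}
        for cohort, table in (("primary", primary_table), ("validation", validation_table)):
            X, y = _split_group(table, gid)
            scores = signature.radiomics_score(model, X)
            roc = evaluate.roc_analysis(scores, y)
            per_cohort[cohort] = {"scores": scores, "labels": y, "roc": roc}
        if config.reuse_primary_cutoff:
            cut = per_cohort["primary"]["roc"].cutoff
            v = per_cohort["validation"]
            pred = v["scores"] >= cut
            y = v["labels"]
            v["roc"].cutoff = cut
            v["roc"].sensitivity = float((pred & y).sum() / y.sum())
            v["roc"].specificity = float((~pred & ~y).sum() / (~y).sum())
            v["roc"].accuracy = float((pred == y).mean())
        out[gid] = per_cohort
    return out


def compare_groups(
    evaluated: dict[int, dict],
    pair: tuple[int, int],
    cohort: str,
) -> dict:
    """Paired DeLong + NRI for one (group_a, group_b) pair in one cohort.

    The "new" model in the NRI is group_a's signature, so a positive total
    means group_a reclassifies better than group_b.
    """
    a, b = pair
    ea, eb = evaluated[a][cohort], evaluated[b][cohort]
    labels = ea["labels"]
    if not np.array_equal(labels, eb["labels"]):
        raise ValueError(f"groups {a} and {b} are not paired on the same subjects")
    auc_a, auc_b, z, p = evaluate.delong_paired(ea["scores"], eb["scores"], labels)
    pred_new = ea["scores"] >= ea["roc"].cutoff
    pred_old = eb["scores"] >= eb["roc"].cutoff
    res = evaluate.nri(pred_old, pred_new, labels)
    return {
        "pair": pair,
        "cohort": cohort,
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delta_auc": auc_a - auc_b,
        "delong_z": z,
        "delong_p": p,
        "nri": res,
    }


@dataclass
class StudyReport:
    """Everything the pipeline computed, plus tabular views."""

    config: PipelineConfig
    screening: dict[int, pd.DataFrame]
    models: dict[int, signature.SignatureModel]
    evaluated: dict[int, dict]
    comparisons: list[dict]

    def performance_table(self) -> pd.DataFrame:
        """Per-group AUC/CI/sensitivity/specificity/accuracy, both cohorts."""
        rows = []
        for gid, per_cohort in self.evaluated.items():
            for cohort, e in per_cohort.items():
                r = e["roc"]
                rows.append(
                    {
                        "group": gid,
                        "cohort": cohort,
                        "AUC": r.auc,
                        "CI95_low": r.ci95[0],
                        "CI95_high": r.ci95[1],
                        "SEN": r.sensitivity,
                        "SPE": r.specificity,
                        "Accuracy": r.accuracy,
                        "cutoff": r.cutoff,
                    }
                )
        return pd.DataFrame(rows)

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "comparison": f"{c['pair'][0]} vs. {c['pair'][1]}",
                    "cohort": c["cohort"],
                    "delta_AUC": c["delta_auc"],
                    "delong_p": c["delong_p"],
                    "NRI_events": c["nri"].nri_events,
                    "NRI_nonevents": c["nri"].nri_nonevents,
                    "NRI_total": c["nri"].total,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.performance_table().round(3).to_csv(outdir / "performance.csv", index=False)
        self.comparison_table().round(3).to_csv(outdir / "comparisons.csv", index=False)
        for gid, scr in self.screening.items():
            scr.to_csv(outdir / f"screening_group{gid}.csv")
        for gid, model in self.models.items():
            model.to_json(outdir / f"signature_group{gid}.json")
        run_log = {
            "config": {
                k: v for k, v in asdict(self.config).items() if not isinstance(v, dict)
            },
            "selected_per_group": {g: m.selected for g, m in self.models.items()},
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
        return outdir


def run_study(config: PipelineConfig | None = None) -> StudyReport:
    """Run the whole synthetic study once and return the report bundle."""
    config = config or PipelineConfig()
    primary = simulate_cohort(config.cohort_spec("primary"))
    validation = simulate_cohort(config.cohort_spec("validation", seed_offset=1))
    primary_table = extract_cohort_features(
        primary, ng=config.ng, sigmas=config.sigmas, hu_window=config.hu_window
    )
    fitted = fit_group_signatures(primary_table, config)  # validation untouched
    validation_table = extract_cohort_features(
        validation, ng=config.ng, sigmas=config.sigmas, hu_window=config.hu_window
    )
    evaluated = evaluate_groups(fitted, primary_table, validation_table, config)
    comparisons = [
        compare_groups(evaluated, pair, cohort)
        for pair in config.comparisons
        for cohort in ("primary", "validation")
    ]
    return StudyReport(
        config=config,
        screening={g: b["screening"] for g, b in fitted.items()},
        models={g: b["model"] for g, b in fitted.items()},
        evaluated=evaluated,
        comparisons=comparisons,
    )
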
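"""Nested subject-wise cross-validation, subject-level metrics and bootstrap CIs.

Evaluation follows the leakage-safe protocol for epoched EEG:

* the outer loop is a stratified five-fold split of *subjects*, so all of
  a subject's epochs land entirely in either the training or the test
  side of every fold;
* inside each outer training set, stability-driven feature selection
  (fold-wise permutation importances over inner grouped folds, scored by
  mu/(sigma+eps)) picks the feature subset, and a grid search over inner
  grouped folds tunes the classifier (SVM-RBF or random forest);
* feature standardisation is part of the estimator pipeline, hence fitted
  on training folds only;
* per-epoch probabilities are averaged into one probability per subject,
  and accuracy / recall / specificity / AUC are computed at the subject
  level from out-of-fold predictions, with percentile bootstrap CIs over
  subjects.

The positive class is the patient group ("P"): recall is sensitivity for
patients, specificity the true-negative rate for controls.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError, ParameterError
from .network import FeatureTable
from .stability import (
    DEFAULT_EPS,
    StabilityRanking,
    make_fold_records,
    permutation_importance,
    select_stable,
    shapley_attribution,
    stability_score,
)

__all__ = [
    "CVConfig",
    "SubjectPrediction",
    "MetricsReport",
    "NestedCVResult",
    "outer_folds",
    "fit_with_inner_cv",
    "nested_cv",
    "aggregate_subject",
    "compute_metrics",
    "bootstrap_ci",
    "group_summary_test",
]

logger = logging.getLogger("netstab")


@dataclass
class CVConfig:
    """Nested cross-validation settings."""

    outer_folds: int = 5
    inner_folds: int = 3
    model: str = "svm_rbf"  # "svm_rbf" | "random_forest"
    svm_grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {"C": [0.1, 1.0, 10.0, 100.0],
                                 "gamma": [1e-3, 1e-2, 1e-1, 1.0]}
    )
    rf_grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {"n_estimators": [100, 300],
                                 "max_depth": [None, 5, 10]}
    )
    seed: int = 0
    aggregation: str = "mean_prob"
    decision_threshold: float = 0.5
    n_select: int = 10
    n_repeats: int = 10
    eps: float = DEFAULT_EPS
    bootstrap_iterations: int = 10_000
    positive_label: str = "P"
    compute_shap: bool = True
    # probe family: "naive_bayes" | "logistic" | "random_forest" | "match"
    importance_model: str = "naive_bayes"
    importance_scoring: str = "neg_log_loss"

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ConfigError("outer_folds must be >= 2")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds must be >= 2")
        if self.model not in ("svm_rbf", "random_forest"):
            raise ConfigError(f"unknown model {self.model!r}")
        grid = self.svm_grid if self.model == "svm_rbf" else self.rf_grid
        if any(len(v) == 0 for v in grid.values()):
            raise ConfigError("hyperparameter grids must be non-empty")
        if self.aggregation != "mean_prob":
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if not (0 < self.decision_threshold < 1):
            raise ConfigError("decision_threshold must be in (0, 1)")


@dataclass
class SubjectPrediction:
    subject_id: str
    true_label: str
    probability: float  # P(positive class)
    fold: int


@dataclass
class MetricsReport:
    """Per-fold and pooled subject-level classification metrics."""

    pooled: dict[str, float]
    per_fold: list[dict[str, float]]
    fold_sd: dict[str, float]
    ci: dict[str, tuple[float, float]]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "pooled": self.pooled,
            "per_fold": self.per_fold,
            "fold_sd": self.fold_sd,
            "ci95": {k: list(v) for k, v in self.ci.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self, model_name: str = "model") -> str:
        """Aligned table: Model, Accuracy, Recall, Specificity, AUC (% +- fold SD)."""
        p, sd = self.pooled, self.fold_sd
        def pct(key: str) -> str:
            return f"{100 * p[key]:.1f} +- {100 * sd.get(key, 0.0):.1f}"
        rows = [
            ("Model", "Accuracy (%)", "Recall (%)", "Specificity (%)", "AUC"),
            (
                model_name,
                pct("accuracy"),
                pct("recall"),
                pct("specificity"),
                f"{p['auc']:.3f} +- {sd.get('auc', 0.0):.3f}",
            ),
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
        )


@dataclass
class FitResult:
    model: Pipeline
    best_params: dict
    selected_features: list[str]
    ranking: StabilityRanking
    records: pd.DataFrame


@dataclass
class NestedCVResult:
    predictions: list[SubjectPrediction]
    metrics: MetricsReport
    ranking: StabilityRanking  # cross-fold aggregate of fold-level importances
    fold_details: list[dict]
    shap_summary: pd.DataFrame | None


def outer_folds(
    subject_ids: Sequence[str],
    labels: Sequence[str],
    k: int,
    seed: int | None = 0,
) -> list[tuple[list[str], list[str]]]:
    """Stratified partition of subjects into k disjoint test sets."""
    subject_ids = list(subject_ids)
    labels = list(labels)
    if len(set(subject_ids)) != len(subject_ids):
        raise DataError("subject IDs must be unique")
    if k > len(subject_ids):
        raise ParameterError(f"k={k} exceeds the {len(subject_ids)} subjects")
    counts = pd.Series(labels).value_counts()
    if k > counts.min():
        raise ParameterError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(subject_ids)
    folds = []
    for train_idx, test_idx in skf.split(ids, np.asarray(labels)):
        folds.append((ids[train_idx].tolist(), ids[test_idx].tolist()))
    return folds


def _make_estimator(
    cfg: CVConfig, seed: int, probability: bool = False
) -> tuple[Pipeline, dict]:
    if cfg.model == "svm_rbf":
        clf = SVC(kernel="rbf", probability=probability, random_state=seed)
        grid = {f"clf__{k}": list(v) for k, v in cfg.svm_grid.items()}
    else:
        clf = RandomForestClassifier(random_state=seed)
        grid = {f"clf__{k}": list(v) for k, v in cfg.rf_grid.items()}
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return pipe, grid


def _make_probe(cfg: CVConfig, seed: int):
    """Importance-probe model for stability selection.

    The probe is the model whose permutation importance drives selection;
    the tuned classifier itself is fitted afterwards on the selected
    columns.  The default is Gaussian naive Bayes: with far more features
    than training subjects, flexible multivariate models split credit
    erratically across clusters of correlated features, so their fold-wise
    permutation importances are dominated by credit-assignment noise.  A
    conditionally independent probabilistic model scores each feature by
    its own discriminative content, which is what a cross-fold stability
    ranking needs to be reproducible.
    """
    if cfg.importance_model == "naive_bayes":
        return GaussianNB()
    if cfg.importance_model == "logistic":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(C=1.0, max_iter=5000))]
        )
    if cfg.importance_model == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    probe, _ = _make_estimator(cfg, seed, probability=True)
    return probe


def _subject_label_map(table: FeatureTable) -> tuple[list[str], list[str]]:
    df = pd.DataFrame({"s": table.subjects, "y": table.labels})
    per = df.drop_duplicates("s")
    if per["s"].duplicated().any() or df.groupby("s")["y"].nunique().max() > 1:
        raise DataError("a subject carries conflicting labels")
    return per["s"].tolist(), per["y"].tolist()


def _rows_for_subjects(table: FeatureTable, subjects: Sequence[str]) -> np.ndarray:
    wanted = set(subjects)
    return table.subjects.isin(wanted).to_numpy()


def _grouped_row_folds(
    table: FeatureTable, row_mask: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified subject folds expressed as row-index splits within a mask."""
    sub = table.subjects[row_mask]
    lab = table.labels[row_mask]
    per = pd.DataFrame({"s": sub, "y": lab}).drop_duplicates("s")
    folds = outer_folds(per["s"].tolist(), per["y"].tolist(), k, seed)
    rows = np.flatnonzero(row_mask)
    local_subjects = sub.to_numpy()
    out = []
    for train_s, test_s in folds:
        tr = np.flatnonzero(np.isin(local_subjects, train_s))
        te = np.flatnonzero(np.isin(local_subjects, test_s))
        out.append((tr, te))
    return out


def fit_with_inner_cv(
    train_table: FeatureTable, cfg: CVConfig, seed: int | None = None
) -> FitResult:
    """Stability selection + grid search inside one training set.

    Inner grouped folds are used twice: to collect fold-wise permutation
    importances for the stability score, and to tune hyperparameters over
    the selected features.  The returned model is refit on the full
    training data (standardiser included, so nothing leaks outside).
    """
    seed = cfg.seed if seed is None else seed
    y = train_table.labels
    class_counts = y.groupby(train_table.subjects.to_numpy()).first().value_counts()
    if len(class_counts) < 2:
        raise DataError("training set contains a single class")
    if class_counts.min() < 2:
        raise DataError("need >= 2 subjects per class in the training set")

    n_inner = min(cfg.inner_folds, int(class_counts.min()))
    all_mask = np.ones(train_table.n_rows, dtype=bool)
    inner = _grouped_row_folds(train_table, all_mask, n_inner, seed)

    # fold-wise permutation importances on held-out inner subjects
    X = train_table.features
    probe = _make_probe(cfg, seed)
    importances = []
    for i, (tr, te) in enumerate(inner):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            probe.fit(X.iloc[tr].to_numpy(), y.iloc[tr])
        imp = permutation_importance(
            probe, X.iloc[te], y.iloc[te],
            n_repeats=cfg.n_repeats, seed=seed + i,
            scoring=cfg.importance_scoring,
        )
        importances.append(imp)
    records = make_fold_records(importances, estimator="permutation")
    ranking = stability_score(records, eps=cfg.eps)
    k = min(cfg.n_select, X.shape[1])
    selected = select_stable(ranking, k)

    # tune by held-out log-loss of the calibrated probabilities: the final
    # decision averages probabilities across epochs, so the grid must be
    # scored on probability quality, not hard-label accuracy (which ties
    # across most of the grid on separable folds)
    estimator, grid = _make_estimator(cfg, seed, probability=True)
    search = GridSearchCV(
        estimator, grid, scoring="neg_log_loss", cv=inner, refit=False,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        search.fit(X[selected].to_numpy(), y)
        final, _ = _make_estimator(cfg, seed, probability=True)
        final.set_params(**search.best_params_)
        final.fit(X[selected].to_numpy(), y)
    return FitResult(
        model=final,
        best_params=search.best_params_,
        selected_features=selected,
        ranking=ranking,
        records=records,
    )


def aggregate_subject(epoch_probs: Sequence[float]) -> float:
    """Mean of a subject's per-epoch probabilities."""
    probs = np.asarray(epoch_probs, dtype=float)
    if probs.size == 0:
        raise DataError("no epoch probabilities to aggregate")
    if probs.min() < 0 or probs.max() > 1:
        raise DataError("probabilities must lie in [0, 1]")
    return float(probs.mean())


def compute_metrics(
    predictions: Sequence[SubjectPrediction],
    threshold: float = 0.5,
    positive_label: str = "P",
) -> dict[str, float]:
    """Subject-level accuracy, recall, specificity and tie-corrected AUC."""
    if len(predictions) == 0:
        raise DataError("no predictions")
    y = np.array([p.true_label == positive_label for p in predictions])
    probs = np.array([p.probability for p in predictions])
    if y.all() or not y.any():
        raise DataError("metrics undefined with a single class in the truth")
    pred = probs >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "recall": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": float(roc_auc_score(y, probs)),
    }


def bootstrap_ci(
    predictions: Sequence[SubjectPrediction],
    statistic: str = "accuracy",
    n_boot: int = 10_000,
    seed: int = 0,
    threshold: float = 0.5,
    positive_label: str = "P",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subjects for accuracy or AUC.

    Resamples subjects with replacement; resamples lacking one of the
    classes are redrawn (the statistic is undefined there).
    """
    if statistic not in ("accuracy", "auc"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be noisy", UserWarning)
    y = np.array([p.true_label == positive_label for p in predictions])
    probs = np.array([p.probability for p in predictions])
    if y.all() or not y.any():
        raise DataError(f"{statistic} undefined on the original sample")
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    # redraw resamples that lost a class
    for _ in range(1000):
        yb = y[idx]
        bad = np.flatnonzero(yb.all(axis=1) | (~yb).all(axis=1))
        if bad.size == 0:
            break
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
    yb = y[idx]
    pb = probs[idx]
    if statistic == "accuracy":
        vals = (((pb >= threshold) == yb).mean(axis=1))
    else:
        ranks = stats.rankdata(pb, axis=1)
        n_pos = yb.sum(axis=1)
        n_neg = n - n_pos
        pos_rank_sum = np.where(yb, ranks, 0.0).sum(axis=1)
        vals = (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def nested_cv(
    table: FeatureTable, cfg: CVConfig, truth_hint: Sequence[str] = ()
) -> NestedCVResult:
    """Full nested evaluation of a feature table.

    Stability selection and hyperparameter tuning run strictly inside each
    outer training set.  The reported global ranking aggregates, per outer
    fold, the mean of that fold's inner importances, then scores mu/sigma
    across the outer folds — so it reflects reproducibility across the
    resampled training sets.
    """
    subjects, labels = _subject_label_map(table)
    folds = outer_folds(subjects, labels, cfg.outer_folds, cfg.seed)

    predictions: list[SubjectPrediction] = []
    fold_details: list[dict] = []
    fold_importances: list[pd.Series] = []
    shap_frames: list[pd.DataFrame] = []
    seen: set[str] = set()
    for f, (train_s, test_s) in enumerate(folds):
        overlap = set(train_s) & set(test_s)
        assert not overlap, f"subject-level leakage in fold {f}: {sorted(overlap)}"
        assert not (set(test_s) & seen), "a subject appears in two test folds"
        seen |= set(test_s)

        tr_mask = _rows_for_subjects(table, train_s)
        te_mask = _rows_for_subjects(table, test_s)
        train_tab = FeatureTable(
            features=table.features[tr_mask].reset_index(drop=True),
            labels=table.labels[tr_mask].reset_index(drop=True),
            subjects=table.subjects[tr_mask].reset_index(drop=True),
        )
        fit = fit_with_inner_cv(train_tab, cfg, seed=cfg.seed + 1000 * (f + 1))
        # one importance value per feature per outer fold: the mean of the
        # fold's inner estimates
        fold_importances.append(fit.records.groupby("feature")["value"].mean())

        Xte = table.features[te_mask][fit.selected_features]
        proba = fit.model.predict_proba(Xte.to_numpy())
        classes = list(fit.model.classes_)
        col = classes.index(cfg.positive_label)
        p_pos = proba[:, col]
        te_subjects = table.subjects[te_mask].to_numpy()
        te_labels = table.labels[te_mask].to_numpy()
        for sid in test_s:
            rows = te_subjects == sid
            prob = aggregate_subject(p_pos[rows])
            predictions.append(
                SubjectPrediction(sid, str(te_labels[rows][0]), prob, f)
            )
        logger.info(
            "fold %d: %d train / %d test subjects, params=%s, features=%s",
            f, len(train_s), len(test_s), fit.best_params, fit.selected_features,
        )
        fold_details.append(
            {
                "fold": f,
                "test_subjects": list(test_s),
                "best_params": fit.best_params,
                "selected_features": fit.selected_features,
            }
        )
        if cfg.compute_shap:
            vals, base = shapley_attribution(
                fit.model,
                Xte,
                background=train_tab.features[fit.selected_features],
                positive_label=cfg.positive_label,
                seed=cfg.seed + f,
            )
            shap_frames.append(
                pd.DataFrame(
                    {"feature": fit.selected_features,
                     "mean_abs_shap": np.abs(vals).mean(axis=0),
                     "fold": f, "base_value": base}
                )
            )

    assert len({p.subject_id for p in predictions}) == len(subjects), (
        "out-of-fold predictions must cover every subject exactly once"
    )

    pooled = compute_metrics(
        predictions, cfg.decision_threshold, cfg.positive_label
    )
    per_fold = []
    for f in range(len(folds)):
        fold_preds = [p for p in predictions if p.fold == f]
        try:
            per_fold.append(
                {"fold": f, **compute_metrics(
                    fold_preds, cfg.decision_threshold, cfg.positive_label)}
            )
        except DataError:  # pragma: no cover — stratification prevents this
            per_fold.append({"fold": f})
    keys = ("accuracy", "recall", "specificity", "auc")
    fold_sd = {
        k: float(np.std([m[k] for m in per_fold if k in m], ddof=1))
        for k in keys
    }
    ci = {
        k: bootstrap_ci(
            predictions, k, cfg.bootstrap_iterations, cfg.seed,
            cfg.decision_threshold, cfg.positive_label,
        )
        for k in ("accuracy", "auc")
    }
    metrics = MetricsReport(pooled=pooled, per_fold=per_fold, fold_sd=fold_sd, ci=ci)
    global_ranking = stability_score(
        make_fold_records(fold_importances, estimator="permutation"), eps=cfg.eps
    )
    shap_summary = (
        pd.concat(shap_frames, ignore_index=True) if shap_frames else None
    )
    return NestedCVResult(
        predictions=predictions,
        metrics=metrics,
        ranking=global_ranking,
        fold_details=fold_details,
        shap_summary=shap_summary,
    )


def group_summary_test(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> dict[str, float]:
    """Welch's t-test and pooled-SD Cohen's d from summary statistics.

    Returns the signed t statistic (group 1 minus group 2), the
    Welch-Satterthwaite degrees of freedom, the two-sided p-value and
    Cohen's d with the pooled standard deviation.  Note that statistics
    recomputed from *rounded* summaries can differ in the last digit from
    values computed on raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 in both groups")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ParameterError("need positive variance in at least one group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    d = (m1 - m2) / sp
    return {
        "welch_t": float(t),
        "welch_df": float(df),
        "p_value": float(p),
        "cohen_d": float(d),
    }
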
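"""Stability-driven feature selection: fold-wise importances and the
mean/dispersion stability score.

Feature importance alone is a fragile basis for selection in small
cohorts: a feature can look highly predictive in one data partition and
irrelevant in the next.  This module therefore scores each feature by the
*consistency* of its importance across cross-validation folds,

    Stability_f = mu_f / (sigma_f + eps),

where mu_f and sigma_f are the mean and sample standard deviation of the
feature's fold-wise importances and eps (default 1e-9) merely guards the
division when sigma_f = 0.  High scores mark features that are both
discriminative (large mu) and reproducible under resampling (small
sigma); selection retains the top-k by score.

Two importance estimators are provided:

* :func:`permutation_importance` — mean performance drop when one feature
  column is shuffled (scikit-learn's estimator; drives selection);
* :func:`shapley_attribution` — additive per-sample Shapley values of the
  model's positive-class probability, computed exactly by coalition
  enumeration for small feature sets (interventional value function:
  features outside the coalition are marginalised over a background
  sample) and by permutation sampling otherwise.  Used for reporting and
  cross-checking the permutation ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError, ParameterError

__all__ = [
    "StabilityRanking",
    "permutation_importance",
    "shapley_attribution",
    "stability_score",
    "select_stable",
    "make_fold_records",
]

#: Default guard constant; negligible at realistic importance scales.
DEFAULT_EPS = 1e-9


@dataclass
class StabilityRanking:
    """Per-feature mean importance, dispersion and stability score.

    ``table`` has columns feature / mu / sigma / score, sorted by
    descending score (ties: larger mu first, then feature name).
    """

    table: pd.DataFrame
    eps: float = DEFAULT_EPS

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={
                "feature": "feature",
                "mu": "mean_importance",
                "sigma": "sd",
                "score": "stability_score",
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _binary_truth(model, y) -> np.ndarray:
    classes = list(model.classes_)
    if len(classes) != 2:
        raise DataError("permutation importance implemented for binary labels")
    return np.asarray(y) == classes[1]


def _model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous ranking scores for AUC: decision function or probability."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    return np.asarray(model.predict_proba(X))[:, -1]


def _auc(y_pos: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Tie-corrected rank AUC; vectorised over leading axes of ``scores``."""
    scores = np.atleast_2d(scores)
    ranks = _stats.rankdata(scores, axis=-1)
    n_pos = int(y_pos.sum())
    n_neg = y_pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined with single-class truth")
    pos_sum = ranks[..., y_pos].sum(axis=-1)
    return (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: Sequence,
    n_repeats: int = 10,
    seed: int | None = None,
    scoring: str = "neg_log_loss",
) -> pd.Series:
    """Mean drop in held-out score when each column is shuffled, per feature.

    importance_f = baseline score - mean over repeats of the score with
    column f permuted.  A label-independent column has importance ~0 and a
    constant column exactly 0.  Features are scored in batched model calls
    (one prediction covers many permutations), so the cost scales with the
    number of batches rather than features x repeats.

    ``scoring``:

    * ``neg_log_loss`` (default) — negative log-likelihood of the held-out
      labels under the model's probabilities.  Strictly proper, so it keeps
      discriminating between features even when the hard-label accuracy or
      the ranking AUC is saturated at its ceiling, which happens quickly on
      small validation folds with several redundant informative features.
    * ``roc_auc`` — rank AUC of the model's continuous scores.
    * ``accuracy`` — hard-label accuracy.
    """
    if scoring not in ("neg_log_loss", "roc_auc", "accuracy"):
        raise ParameterError(f"unsupported scoring {scoring!r}")
    rng = np.random.default_rng(seed)
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    n, m = Xv.shape
    y_pos = _binary_truth(model, y)

    if scoring == "neg_log_loss":
        if not hasattr(model, "predict_proba"):
            raise DataError("neg_log_loss scoring needs predict_proba")

        def _nll(Z: np.ndarray, lead: tuple[int, ...]) -> np.ndarray:
            p = np.asarray(model.predict_proba(Z))[:, 1].reshape(*lead, n)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = np.where(y_pos, np.log(p), np.log1p(-p))
            return ll.mean(axis=-1)

        base = float(_nll(Xv, ()))

        def evaluate(Z: np.ndarray, k: int) -> np.ndarray:
            return _nll(Z, (k, n_repeats)).mean(axis=-1)
    elif scoring == "roc_auc":
        base = float(_auc(y_pos, _model_scores(model, Xv))[0])

        def evaluate(Z: np.ndarray, k: int) -> np.ndarray:
            return _auc(y_pos, _model_scores(model, Z).reshape(k, n_repeats, n)
                        ).mean(axis=-1)
    else:
        y_arr = np.asarray(y)
        base = float((np.asarray(model.predict(Xv)) == y_arr).mean())

        def evaluate(Z: np.ndarray, k: int) -> np.ndarray:
            eq = np.asarray(model.predict(Z)).reshape(k, n_repeats, n) == y_arr
            return eq.mean(axis=(1, 2))

    importances = np.empty(m)
    # batch features so each chunk costs a single model call
    chunk = max(1, 200_000 // max(1, n_repeats * n))
    for start in range(0, m, chunk):
        feats = range(start, min(start + chunk, m))
        k = len(feats)
        stacked = np.repeat(Xv[None, None, :, :], n_repeats, axis=1)
        stacked = np.repeat(stacked, k, axis=0)  # (k, R, n, m)
        for fi, f in enumerate(feats):
            for r in range(n_repeats):
                stacked[fi, r, :, f] = Xv[rng.permutation(n), f]
        scores = evaluate(stacked.reshape(k * n_repeats * n, m), k)
        importances[list(feats)] = base - scores
    return pd.Series(importances, index=X.columns, name="importance")


def _positive_proba(model, X: np.ndarray, positive_label=None) -> np.ndarray:
    if not hasattr(model, "predict_proba"):
        raise DataError("Shapley attribution requires a probabilistic model")
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", range(proba.shape[1])))
    col = classes.index(positive_label) if positive_label in classes else len(classes) - 1
    return proba[:, col]


def shapley_attribution(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame | None = None,
    positive_label=None,
    max_exact: int = 12,
    n_permutations: int = 200,
    max_background: int = 32,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Shapley values of the positive-class probability for each row of X.

    The value of a coalition S is the expected model output when features
    in S take the explained row's values and the rest are drawn from the
    background sample (marginal expectation).  For up to ``max_exact``
    features all 2^M coalitions are enumerated, which makes the attribution
    exact: base value + sum of attributions equals the prediction to
    machine precision.  Beyond that, marginal contributions are averaged
    over random feature permutations.

    Returns ``(values, base)`` with ``values`` of shape (n_rows, M) and
    ``base`` the mean prediction on the background.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    n, m = Xv.shape
    bg = X if background is None else background
    bgv = bg.to_numpy(dtype=float)
    if len(bgv) > max_background:
        bgv = bgv[rng.choice(len(bgv), size=max_background, replace=False)]
    nb = len(bgv)

    rep = np.repeat(Xv, nb, axis=0)
    tiled = np.tile(bgv, (n, 1)) if n else bgv[:0]

    def coalition_value(mask: np.ndarray) -> np.ndarray:
        # E_b f(x_S, b_notS) for every explained row; one batched predict
        mixed = np.where(mask, rep, tiled)
        out = _positive_proba(model, mixed, positive_label)
        return out.reshape(n, nb).mean(axis=1)

    if m <= max_exact:
        values = np.zeros((n, m))
        n_coal = 2**m
        masks = (
            (np.arange(n_coal)[:, None] >> np.arange(m)[None, :]) & 1
        ).astype(bool)
        v = np.empty((n_coal, n))
        # evaluate coalitions in batches: one model call covers many coalitions
        rows_per = max(1, n * nb)
        chunk = max(1, 200_000 // rows_per)
        for start in range(0, n_coal, chunk):
            stop = min(start + chunk, n_coal)
            mixed = np.where(masks[start:stop, None, :], rep[None, :, :], tiled)
            out = _positive_proba(
                model, mixed.reshape(-1, m), positive_label
            ).reshape(stop - start, n, nb)
            v[start:stop] = out.mean(axis=2)
        fact = [factorial(i) for i in range(m + 1)]
        for j in range(m):
            for s in range(2**m):
                if (s >> j) & 1:
                    continue
                size = bin(s).count("1")
                w = fact[size] * fact[m - size - 1] / fact[m]
                values[:, j] += w * (v[s | (1 << j)] - v[s])
        # v(empty set) is the background-mean prediction, identical per row
        base = float(v[0][0]) if n else float(
            _positive_proba(model, bgv, positive_label).mean()
        )
        return values, base

    # permutation-sampling estimator for larger feature sets
    values = np.zeros((n, m))
    mask = np.zeros(m, dtype=bool)
    base = float(_positive_proba(model, bgv, positive_label).mean())
    for _ in range(n_permutations):
        order = rng.permutation(m)
        mask[:] = False
        prev = np.full(n, base)
        for j in order:
            mask[j] = True
            cur = coalition_value(mask.copy())
            values[:, j] += cur - prev
            prev = cur
    values /= n_permutations
    return values, base


def make_fold_records(
    importances_by_fold: Sequence[pd.Series], estimator: str = "permutation"
) -> pd.DataFrame:
    """Stack per-fold importance Series into a tidy (feature, fold, value) frame."""
    frames = []
    for fold, imp in enumerate(importances_by_fold):
        frames.append(
            pd.DataFrame(
                {
                    "feature": imp.index,
                    "fold": fold,
                    "estimator": estimator,
                    "value": imp.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def stability_score(records: pd.DataFrame, eps: float = DEFAULT_EPS) -> StabilityRanking:
    """Per-feature mu, sigma across folds and the score mu/(sigma + eps).

    ``records`` must carry columns feature/fold/value for a single
    importance estimator; sigma is the sample (n-1) standard deviation.
    """
    if eps <= 0:
        raise ParameterError(f"eps must be > 0, got {eps}")
    required = {"feature", "fold", "value"}
    if not required.issubset(records.columns):
        raise DataError(f"records need columns {sorted(required)}")
    if "estimator" in records.columns and records["estimator"].nunique() > 1:
        raise DataError("records mix importance estimators; score one at a time")
    counts = records.groupby("feature")["fold"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DataError(
            f"need >= 2 folds per feature (sigma undefined); offending: {bad[:5]}"
        )
    grouped = records.groupby("feature")["value"]
    mu = grouped.mean()
    sigma = grouped.std(ddof=1)
    score = mu / (sigma + eps)
    table = pd.DataFrame(
        {"feature": mu.index, "mu": mu.to_numpy(), "sigma": sigma.to_numpy(),
         "score": score.to_numpy()}
    )
    table = table.sort_values(
        by=["score", "mu", "feature"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return StabilityRanking(table=table, eps=eps)


def select_stable(ranking: StabilityRanking, k: int) -> list[str]:
    """Top-k feature names by stability score (tie-breaks already applied)."""
    n = len(ranking.table)
    if not (1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    return ranking.features[:k]
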
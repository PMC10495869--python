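"""Gradient-boosted-tree training and repeated cross-validated evaluation.

Classifiers are LightGBM tree ensembles. Performance is estimated under
repeated stratified k-fold cross-validation (default 5-fold x 3 repetitions)
with four metrics per held-out fold: AUC, sensitivity, specificity and
positive predictive value. Sensitivity/specificity/PPV require a probability
cut-point, which the protocol leaves open; the default rule maximizes
Youden's J on the training-fold predictions (a fixed 0.5 rule is available).
Feature importance is the LightGBM split count (number of times a feature is
used as a split node), rescaled to 0-100.

All featurization that involves fitted quantities (PAC thresholds) is
performed inside each fold on the training portion only, via the
``feature_builder`` callback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, RepeatedStratifiedKFold, StratifiedKFold

#: Fixed hyperparameters suited to cohorts of ~100-1000 participants with
#: ~60 features: shallow trees, slow learning rate, mild row/column
#: subsampling, and coarse histogram binning (EMA features are counts and
#: bounded scales; 15 bins regularize continuous summaries and keep split
#: opportunities comparable across feature cardinalities).
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 300,
    "learning_rate": 0.05,
    "num_leaves": 7,
    "max_depth": -1,
    "min_child_samples": 20,
    "subsample": 0.9,
    "subsample_freq": 1,
    "colsample_bytree": 0.8,
    "max_bin": 15,
}

#: Default random-search space for optional hyperparameter tuning.
DEFAULT_SEARCH_SPACE: dict[str, Sequence] = {
    "n_estimators": (100, 200, 300, 500),
    "learning_rate": (0.02, 0.05, 0.1),
    "num_leaves": (3, 7, 15, 31),
    "min_child_samples": (2, 5, 10, 20),
    "subsample": (0.7, 0.9, 1.0),
    "colsample_bytree": (0.6, 0.8, 1.0),
}

METRIC_NAMES: tuple[str, ...] = ("auc", "sensitivity", "specificity", "ppv")


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation layout: stratified k-fold with repetitions, or LOOCV."""

    k: int = 5
    repetitions: int = 3
    stratified: bool = True
    variant: str = "kfold"  # "kfold" | "loocv"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("kfold", "loocv"):
            raise ValueError("variant must be 'kfold' or 'loocv'")
        if self.variant == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for k-fold")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class MetricDistribution:
    """Per-fold metric values plus normal-approximation summaries."""

    folds: pd.DataFrame  # columns: repetition, fold, n_test, threshold, 4 metrics
    scheme: CvScheme | None = None
    skipped: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            vals = self.folds[m].dropna().to_numpy(dtype=float)
            mean = vals.mean() if vals.size else np.nan
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            rows.append(
                {"metric": m, "mean": mean,
                 "ci_lower": mean - 1.96 * se, "ci_upper": mean + 1.96 * se,
                 "n_folds": int(vals.size)}
            )
        return pd.DataFrame(rows)

    def mean(self, metric: str) -> float:
        return float(self.folds[metric].dropna().mean())


def fit_classifier(
    X: pd.DataFrame,
    y: Sequence[int],
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> LGBMClassifier:
    """Fit a LightGBM classifier; deterministic given the seed."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit classifier")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    model = LGBMClassifier(
        **params,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    return model


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def youden_threshold(labels: Sequence[int], scores: Sequence[float]) -> float:
    """The observed score cut-point maximizing J = sensitivity + specificity - 1,
    with ties broken toward the lowest such cut-point."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection requires both classes present")
    best_thr, best_j = None, -np.inf
    for thr in np.unique(scores):  # ascending
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1.0
        if j > best_j:  # strict: keeps the lowest maximizing threshold
            best_j, best_thr = j, float(thr)
    return best_thr


def threshold_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, PPV) with positive = score >= threshold.

    PPV is NaN (with a warning) when no case is predicted positive.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold metrics require both classes present")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives; PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    return sens, spec, ppv


def prevalence_with_ci(labels: Sequence[int]) -> tuple[float, float, float]:
    """Prevalence with a Wald 95% CI, in percent, clipped to [0, 100]."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n == 0:
        raise ValueError("empty label vector")
    p = labels.mean()
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    lo, hi = max(0.0, p - half), min(1.0, p + half)
    return 100 * p, 100 * lo, 100 * hi


def split_importance(model: LGBMClassifier,
                     feature_names: Sequence[str]) -> pd.DataFrame:
    """Split-count feature importance, scaled so the most-used feature
    scores 100 and unsplit features score 0; rank 1 = most important."""
    counts = model.booster_.feature_importance(importance_type="split")
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(feature_names):
        raise ValueError("feature_names length does not match the model")
    top = counts.max()
    scores = 100.0 * counts / top if top > 0 else np.zeros_like(counts)
    out = pd.DataFrame(
        {"feature": list(feature_names), "split_count": counts.astype(int),
         "score": scores}
    )
    out["rank"] = out["split_count"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["rank", "feature"]).reset_index(drop=True)


def averaged_split_importance(
    X: pd.DataFrame,
    y: Sequence[int],
    hyperparams: Mapping | None = None,
    n_models: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-count importance averaged over ``n_models`` refits that differ
    only in the row/column subsampling seed.

    Split-node allocation among correlated features is noisy in a single
    ensemble; averaging over subsampling seeds stabilizes the ranking while
    still measuring importance on the entire data set.
    """
    totals = np.zeros(X.shape[1])
    for j in range(n_models):
        model = fit_classifier(X, y, hyperparams, seed=seed + j)
        totals += model.booster_.feature_importance(importance_type="split")
    counts = totals / n_models
    top = counts.max()
    scores = 100.0 * counts / top if top > 0 else np.zeros_like(counts)
    out = pd.DataFrame({"feature": list(X.columns),
                        "split_count": counts, "score": scores})
    out["rank"] = out["split_count"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["rank", "feature"]).reset_index(drop=True)


def make_fold_assignments(
    ids: Sequence[str], labels: Sequence[int], scheme: CvScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shared (train_ids, test_ids) splits, deterministic given scheme.seed."""
    ids = np.asarray(sorted(ids))
    labels = np.asarray(labels)
    if scheme.variant == "loocv":
        splitter = LeaveOneOut()
        return [(ids[tr], ids[te]) for tr, te in splitter.split(ids)]
    splitter = RepeatedStratifiedKFold(
        n_splits=scheme.k, n_repeats=scheme.repetitions, random_state=scheme.seed
    )
    return [(ids[tr], ids[te]) for tr, te in splitter.split(ids, labels)]


def tune_hyperparams(
    X: pd.DataFrame,
    y: Sequence[int],
    search_space: Mapping[str, Sequence] | None = None,
    n_candidates: int = 25,
    inner_k: int = 3,
    seed: int = 0,
) -> dict:
    """Random-search hyperparameter selection by mean inner-CV AUC.

    Ties are broken toward fewer trees, then fewer leaves (shallower model),
    then candidate order — so the selection is deterministic given the seed.
    """
    space = dict(search_space if search_space is not None else DEFAULT_SEARCH_SPACE)
    if not space:
        raise ValueError("search space is empty")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    keys = sorted(space)
    candidates = []
    seen = set()
    for _ in range(n_candidates):
        cand = {k: space[k][rng.integers(len(space[k]))] for k in keys}
        sig = tuple(cand[k] for k in keys)
        if sig not in seen:
            seen.add(sig)
            candidates.append(cand)
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    results = []
    for order, cand in enumerate(candidates):
        aucs = []
        for tr, te in inner.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError("degenerate inner fold: a class is absent")
            model = fit_classifier(X.iloc[tr], y[tr], cand, seed=seed)
            aucs.append(auc(y[te], model.predict_proba(X.iloc[te])[:, 1]))
        results.append((
            -float(np.mean(aucs)),
            cand.get("n_estimators", DEFAULT_HYPERPARAMS["n_estimators"]),
            cand.get("num_leaves", DEFAULT_HYPERPARAMS["num_leaves"]),
            order,
            cand,
        ))
    results.sort(key=lambda r: r[:4])
    return results[0][4]


def repeated_cv(
    feature_builder: Callable[[np.ndarray, np.ndarray], tuple[pd.DataFrame, pd.DataFrame]],
    labels: pd.Series,
    scheme: CvScheme,
    hyperparams: Mapping | None = None,
    tune: bool = False,
    search_space: Mapping[str, Sequence] | None = None,
    threshold_rule: str = "youden",
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MetricDistribution:
    """Repeated stratified cross-validated evaluation.

    ``feature_builder(train_ids, test_ids)`` must return aligned feature
    tables for the two id sets, with every fitted featurization quantity
    (e.g. PAC thresholds) derived from the training ids only.

    ``labels`` is a binary Series indexed by participant id. For k-fold the
    result has one row per (repetition, fold); for LOOCV the held-out
    predictions are pooled into a single metric row. Folds lacking a class
    are skipped and recorded.
    """
    labels = labels.sort_index()
    ids = labels.index.to_numpy()
    if folds is None:
        folds = make_fold_assignments(ids, labels.to_numpy(), scheme)

    if scheme.variant == "loocv":
        return _loocv(feature_builder, labels, scheme, hyperparams, folds,
                      threshold_rule)

    rows, skipped = [], []
    for i, (train_ids, test_ids) in enumerate(folds):
        rep, fold = divmod(i, scheme.k)
        y_tr = labels.loc[train_ids].to_numpy()
        y_te = labels.loc[test_ids].to_numpy()
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            warnings.warn(f"fold {i}: a class is absent; fold skipped",
                          stacklevel=2)
            skipped.append(i)
            continue
        X_tr, X_te = feature_builder(train_ids, test_ids)
        hp = hyperparams
        if tune:
            hp = tune_hyperparams(X_tr, y_tr, search_space, seed=scheme.seed + i)
        model = fit_classifier(X_tr, y_tr, hp, seed=scheme.seed + i)
        score_te = model.predict_proba(X_te)[:, 1]
        if threshold_rule == "youden":
            # Youden on out-of-fold training predictions: in-sample scores
            # are overfit toward 0/1 and would place the cut-point far from
            # the shrunken held-out probabilities.
            oof = _oof_scores(X_tr, y_tr, hp, seed=scheme.seed + i)
            thr = youden_threshold(y_tr, oof)
        else:
            thr = 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens, spec, ppv = threshold_metrics(y_te, score_te, thr)
        rows.append(
            {"repetition": rep, "fold": fold, "n_test": len(test_ids),
             "threshold": thr, "auc": auc(y_te, score_te),
             "sensitivity": sens, "specificity": spec, "ppv": ppv}
        )
    return MetricDistribution(pd.DataFrame(rows), scheme=scheme, skipped=skipped)


def _oof_scores(X: pd.DataFrame, y: np.ndarray, hyperparams, seed: int,
                n_splits: int = 3) -> np.ndarray:
    """Out-of-fold predicted probabilities on the training portion."""
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for tr, te in inner.split(X, y):
        if len(np.unique(y[tr])) < 2:
            oof[te] = y[tr].mean()
            continue
        model = fit_classifier(X.iloc[tr], y[tr], hyperparams, seed=seed)
        oof[te] = model.predict_proba(X.iloc[te])[:, 1]
    return oof


def _loocv(feature_builder, labels, scheme, hyperparams, folds, threshold_rule):
    """LOOCV: one held-out prediction per participant, pooled before scoring."""
    preds = pd.Series(index=labels.index, dtype=float)
    for i, (train_ids, test_ids) in enumerate(folds):
        y_tr = labels.loc[train_ids].to_numpy()
        X_tr, X_te = feature_builder(train_ids, test_ids)
        model = fit_classifier(X_tr, y_tr, hyperparams, seed=scheme.seed)
        preds.loc[test_ids] = model.predict_proba(X_te)[:, 1]
    y = labels.to_numpy()
    scores = preds.to_numpy()
    thr = youden_threshold(y, scores) if threshold_rule == "youden" else 0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sens, spec, ppv = threshold_metrics(y, scores, thr)
    row = {"repetition": 0, "fold": 0, "n_test": len(y), "threshold": thr,
           "auc": auc(y, scores), "sensitivity": sens, "specificity": spec,
           "ppv": ppv}
    return MetricDistribution(pd.DataFrame([row]), scheme=scheme)
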
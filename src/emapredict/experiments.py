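"""The three study designs: predictor-set comparison, incremental day-overlay
curves, and per-wave evaluation, with Welch t tests and Benjamini-Hochberg
FDR adjustment over fold-level metric values.

Within one experiment every design/window/wave is evaluated on identical
train/test splits, so cross-design metric differences are not confounded by
fold composition. Fold-level metric values from repeated cross-validation
are not independent samples; the t tests are reported in the same spirit as
the study protocol, and the caveat is recorded in each result's metadata.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import build_feature_table, fit_pac_thresholds
from .modeling import (
    METRIC_NAMES,
    CvScheme,
    MetricDistribution,
    make_fold_assignments,
    repeated_cv,
)

#: Conventional "acceptable accuracy" AUC level for the day-overlay curve.
ACCEPTABLE_AUC = 0.70


@dataclass
class ExperimentResult:
    """Evaluations of several designs on shared folds, plus pairwise tests."""

    results: dict[str, MetricDistribution]
    tests: pd.DataFrame
    horizon: str
    metadata: dict = field(default_factory=dict)

    def mean_auc(self, design: str) -> float:
        return self.results[design].mean("auc")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float],
            paired: bool = False) -> tuple[float, float]:
    """Two-sided t test; Welch (unequal variance) unless ``paired``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples")
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def fold_hash(folds: list[tuple[np.ndarray, np.ndarray]]) -> str:
    """Stable digest of a fold layout, for manifests and sharing checks."""
    h = hashlib.sha256()
    for train_ids, test_ids in folds:
        h.update(",".join(map(str, train_ids)).encode())
        h.update(b"|")
        h.update(",".join(map(str, test_ids)).encode())
        h.update(b";")
    return h.hexdigest()[:16]


def ema_feature_builder(daily: pd.DataFrame, window: Iterable[int] | None = None,
                        baseline: pd.DataFrame | None = None):
    """Per-fold featurizer: PAC thresholds fitted on training participants
    only; optionally appends the 7 encoded baseline predictors."""
    window = None if window is None else set(window)

    def build(train_ids: np.ndarray, test_ids: np.ndarray):
        train_daily = daily[daily["participant_id"].isin(set(train_ids))]
        thresholds = fit_pac_thresholds(train_daily, window)
        out = []
        for id_set in (train_ids, test_ids):
            sub = daily[daily["participant_id"].isin(set(id_set))]
            X = build_feature_table(sub, window, thresholds,
                                    participants=list(id_set))
            if baseline is not None:
                X = X.join(baseline, how="left")
            out.append(X)
        return out[0], out[1]

    return build


def baseline_feature_builder(baseline: pd.DataFrame):
    """Featurizer using only the 7 encoded baseline predictors."""

    def build(train_ids: np.ndarray, test_ids: np.ndarray):
        return (baseline.loc[sorted(train_ids)], baseline.loc[sorted(test_ids)])

    return build


def pairwise_tests(results: Mapping[str, MetricDistribution],
                   metrics: Sequence[str] = METRIC_NAMES,
                   paired: bool = False) -> pd.DataFrame:
    """All pairwise Welch t tests per metric, BH-adjusted jointly."""
    labels = list(results)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for m in metrics:
                a = results[la].folds[m].dropna().to_numpy()
                b = results[lb].folds[m].dropna().to_numpy()
                paired_here = paired and len(a) == len(b)
                if len(a) < 2 or len(b) < 2:
                    # e.g. PPV undefined in almost every fold
                    t, p = np.nan, np.nan
                else:
                    t, p = welch_t(a, b, paired=paired_here)
                rows.append({"design_a": la, "design_b": lb, "metric": m,
                             "mean_a": a.mean() if len(a) else np.nan,
                             "mean_b": b.mean() if len(b) else np.nan,
                             "t": t, "p_raw": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = np.nan
        ok = table["p_raw"].notna()
        if ok.any():
            table.loc[ok, "p_adjusted"] = bh_adjust(table.loc[ok, "p_raw"].to_numpy())
    return table


def _evaluate_designs(
    builders: Mapping[str, object],
    labels: pd.Series,
    scheme: CvScheme,
    horizon: str,
    paired: bool = False,
    hyperparams: Mapping | None = None,
) -> ExperimentResult:
    labels = labels.sort_index()
    folds = make_fold_assignments(labels.index, labels.to_numpy(), scheme)
    results = {
        name: repeated_cv(builder, labels, scheme, hyperparams=hyperparams,
                          folds=folds)
        for name, builder in builders.items()
    }
    tests = pairwise_tests(results, paired=paired)
    meta = {
        "fold_hash": fold_hash(folds),
        "scheme": scheme,
        "caveat": "t tests treat fold-level CV metrics as samples; "
                  "fold values are not independent",
    }
    return ExperimentResult(results, tests, horizon, meta)


def compare_predictor_sets(
    daily: pd.DataFrame,
    baseline: pd.DataFrame,
    labels: pd.Series,
    horizon: str,
    scheme: CvScheme,
    window: Iterable[int] | None = None,
    paired: bool = False,
    hyperparams: Mapping | None = None,
) -> ExperimentResult:
    """Evaluate baseline-only, EMA-only, and baseline+EMA predictor sets on
    identical folds; 3 pairwise Welch t tests x 4 metrics, BH-adjusted."""
    builders = {
        "baseline": baseline_feature_builder(baseline),
        "ema": ema_feature_builder(daily, window),
        "baseline_plus_ema": ema_feature_builder(daily, window, baseline=baseline),
    }
    return _evaluate_designs(builders, labels, scheme, horizon, paired,
                             hyperparams)


def incremental_day_curve(
    daily: pd.DataFrame,
    labels: pd.Series,
    horizon: str,
    scheme: CvScheme,
    n_days: int = 25,
    auc_threshold: float = ACCEPTABLE_AUC,
    k_values: Sequence[int] | None = None,
    hyperparams: Mapping | None = None,
) -> tuple[pd.DataFrame, int | None, dict[int, MetricDistribution]]:
    """Mean CV AUC when EMA data from days 1..k are overlaid, k = 1..n_days.

    Returns the curve table, the smallest k whose mean AUC exceeds
    ``auc_threshold`` (None if never crossed), and the per-k distributions.
    Fold assignments are identical across all k.
    """
    labels = labels.sort_index()
    folds = make_fold_assignments(labels.index, labels.to_numpy(), scheme)
    ks = list(k_values) if k_values is not None else list(range(1, n_days + 1))
    rows, dists = [], {}
    for k in ks:
        builder = ema_feature_builder(daily, window=range(1, k + 1))
        dist = repeated_cv(builder, labels, scheme, hyperparams=hyperparams,
                           folds=folds)
        dists[k] = dist
        s = dist.summary().set_index("metric")
        rows.append({"k": k, "mean_auc": s.loc["auc", "mean"],
                     "ci_lower": s.loc["auc", "ci_lower"],
                     "ci_upper": s.loc["auc", "ci_upper"]})
    curve = pd.DataFrame(rows)
    crossed = curve[curve["mean_auc"] > auc_threshold]
    crossing_k = int(crossed["k"].iloc[0]) if len(crossed) else None
    return curve, crossing_k, dists


def wave_days(wave_boundaries: tuple[int, int], n_days: int = 25
              ) -> dict[str, range]:
    b1, b2 = wave_boundaries
    if not (1 <= b1 < b2 < n_days):
        raise ValueError("wave boundaries must satisfy 1 <= b1 < b2 < n_days")
    return {"wave1": range(1, b1 + 1), "wave2": range(b1 + 1, b2 + 1),
            "wave3": range(b2 + 1, n_days + 1)}


def wave_analysis(
    daily: pd.DataFrame,
    labels: pd.Series,
    horizon: str,
    scheme: CvScheme,
    wave_boundaries: tuple[int, int] = (8, 17),
    n_days: int = 25,
    paired: bool = False,
    hyperparams: Mapping | None = None,
) -> ExperimentResult:
    """Evaluate EMA features computed within each wave's days only
    (before / during / after the holiday period), on shared folds."""
    waves = wave_days(wave_boundaries, n_days)
    for name, days in waves.items():
        if len(days) == 0:
            raise ValueError(f"empty wave: {name}")
    builders = {name: ema_feature_builder(daily, window=days)
                for name, days in waves.items()}
    res = _evaluate_designs(builders, labels, scheme, horizon, paired,
                            hyperparams)
    res.metadata["wave_boundaries"] = tuple(wave_boundaries)
    return res
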
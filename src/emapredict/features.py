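"""Person-level feature extraction from daily EMA series.

For each of eight daily series (six mood items, the daily count of distinct
stressful-event categories, and the daily most-stressful worry level) five
time-series summaries are computed per participant: mean, sample SD, OLS
slope on the day index, maximum absolute successive change, and the
probability of acute change (PAC) — the fraction of successive changes at
least as large as a threshold. Together with the cumulative person-specific
frequency of each of the 10 event categories (days endorsed, and days
selected as "most stressful") this yields exactly 60 features per
participant per observation window.

The PAC threshold is not part of the instrument; it is operationalized here
per series as the 90th percentile of the pooled absolute successive
differences across the (training) participants, with a fixed-constant
override. Successive differences are taken between adjacent *retained* days
by default, preserving calendar gaps for the slope regressor.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .schema import (
    BASELINE_PREDICTORS,
    DAILY_SERIES_VARS,
    EVENT_CATEGORIES,
    NSSI_BANDS,
    event_flag_col,
)

logger = logging.getLogger(__name__)

SUMMARY_NAMES: tuple[str, ...] = ("mean", "sd", "slope", "max_change", "pac")

PAC_PERCENTILE = 90.0


class SummarySet(NamedTuple):
    """The five time-series summaries of one person's one series."""

    mean: float
    sd: float
    slope: float
    max_change: float
    pac: float


def feature_columns() -> list[str]:
    """The 60 EMA feature names in canonical order."""
    cols = [f"{var}_{s}" for var in DAILY_SERIES_VARS for s in SUMMARY_NAMES]
    cols += [f"freq_{c}" for c in EVENT_CATEGORIES]
    cols += [f"freq_ms_{c}" for c in EVENT_CATEGORIES]
    return cols


def series_summaries(
    values: Sequence[float],
    day_index: Sequence[int],
    pac_threshold: float,
) -> SummarySet:
    """Compute the five summaries of one ordered daily series.

    Degenerate series follow the single-day policy: with fewer than two
    observations, sd/slope/max_change/pac are 0 (mean is still defined for
    one observation).
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(day_index, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    if y.size != d.size:
        raise ValueError("values and day_index must have equal length")
    if y.size > 1 and not np.all(np.diff(d) > 0):
        raise ValueError("day_index must be strictly increasing")
    if pac_threshold <= 0:
        raise ValueError("pac_threshold must be positive")
    if y.size == 1:
        return SummarySet(float(y[0]), 0.0, 0.0, 0.0, 0.0)
    diffs = np.abs(np.diff(y))
    dc, yc = d - d.mean(), y - y.mean()
    slope = float(dc @ yc / (dc @ dc))
    return SummarySet(
        mean=float(y.mean()),
        sd=float(y.std(ddof=1)),
        slope=slope,
        max_change=float(diffs.max()),
        pac=float((diffs >= pac_threshold).mean()),
    )


def default_pac_threshold(all_series: Iterable[Sequence[float]]) -> float:
    """Threshold for one variable: the 90th percentile (linear interpolation)
    of absolute successive differences pooled over the given series."""
    pooled: list[np.ndarray] = []
    for series in all_series:
        y = np.asarray(series, dtype=float)
        if y.size >= 2:
            pooled.append(np.abs(np.diff(y)))
    if not pooled:
        raise ValueError("no successive differences available")
    return float(np.percentile(np.concatenate(pooled), PAC_PERCENTILE))


def _windowed(daily: pd.DataFrame, window: Iterable[int] | None) -> pd.DataFrame:
    df = daily.sort_values(["participant_id", "day"])
    if window is not None:
        df = df[df["day"].isin(set(window))]
    return df


def _grouped_diffs(df: pd.DataFrame, var: str,
                   calendar_adjacent_only: bool) -> pd.Series:
    g = df.groupby("participant_id", sort=True)
    diffs = g[var].diff()
    if calendar_adjacent_only:
        day_gap = g["day"].diff()
        diffs = diffs.where(day_gap == 1)
    return diffs


def fit_pac_thresholds(
    daily: pd.DataFrame,
    window: Iterable[int] | None = None,
    calendar_adjacent_only: bool = False,
) -> dict[str, float]:
    """Per-series PAC thresholds from pooled absolute successive differences.

    Fit this on training participants only when used inside cross-validation.
    A series whose pooled differences are all zero (or absent) falls back to
    a threshold of 1.0, making its PAC identically 0.
    """
    df = _windowed(daily, window)
    out: dict[str, float] = {}
    for var in DAILY_SERIES_VARS:
        diffs = _grouped_diffs(df, var, calendar_adjacent_only).abs().dropna()
        if len(diffs) == 0 or float(np.percentile(diffs, PAC_PERCENTILE)) <= 0:
            out[var] = 1.0
        else:
            out[var] = float(np.percentile(diffs, PAC_PERCENTILE))
    return out


def event_frequencies(
    daily: pd.DataFrame,
    participant_id: str,
    window: Iterable[int] | None = None,
) -> dict[str, int]:
    """The 20 cumulative person-specific frequencies for one participant:
    per category, the number of retained window days with the category
    endorsed and the number of days it was the most-stressful selection."""
    df = _windowed(daily[daily["participant_id"] == participant_id], window)
    out: dict[str, int] = {}
    for cat in EVENT_CATEGORIES:
        out[f"freq_{cat}"] = int(df[event_flag_col(cat)].sum())
        out[f"freq_ms_{cat}"] = int(df[f"ms_{cat}"].sum())
    return out


def build_feature_table(
    daily: pd.DataFrame,
    window: Iterable[int] | None = None,
    pac_thresholds: Mapping[str, float] | None = None,
    participants: Sequence[str] | None = None,
    calendar_adjacent_only: bool = False,
) -> pd.DataFrame:
    """Build the participants x 60 EMA feature table.

    Parameters
    ----------
    daily
        Output of :func:`emapredict.io.day_aggregate`.
    window
        Day indices to restrict to (a wave or a first-k-days prefix);
        ``None`` uses all retained days.
    pac_thresholds
        Per-series PAC thresholds; when ``None`` they are fitted on the same
        data (acceptable only outside cross-validation).
    participants
        Row universe; participants with no retained day in the window get a
        policy-filled row (all summaries and counts 0) with a logged warning.
    """
    df = _windowed(daily, window)
    if pac_thresholds is None:
        pac_thresholds = fit_pac_thresholds(
            daily, window, calendar_adjacent_only=calendar_adjacent_only
        )

    g = df.groupby("participant_id", sort=True)
    pieces: dict[str, pd.Series] = {}
    n_days = g.size()
    day_sums = g["day"].sum()
    day_sq_sums = (df["day"] ** 2).groupby(df["participant_id"]).sum()

    for var in DAILY_SERIES_VARS:
        gv = g[var]
        mean = gv.mean()
        sd = gv.std(ddof=1)
        # OLS slope on day index via per-group sufficient statistics
        sxy = (df[var] * df["day"]).groupby(df["participant_id"]).sum()
        denom = n_days * day_sq_sums - day_sums**2
        numer = n_days * sxy - day_sums * gv.sum()
        slope = (numer / denom.where(denom != 0)).fillna(0.0)
        diffs = _grouped_diffs(df, var, calendar_adjacent_only).abs()
        key = df["participant_id"]
        max_change = diffs.groupby(key).max()
        thr = float(pac_thresholds[var])
        pac = (diffs >= thr).astype(float).where(diffs.notna()).groupby(key).mean()
        pieces[f"{var}_mean"] = mean
        pieces[f"{var}_sd"] = sd.fillna(0.0)
        pieces[f"{var}_slope"] = slope
        pieces[f"{var}_max_change"] = max_change.fillna(0.0)
        pieces[f"{var}_pac"] = pac.fillna(0.0)

    for cat in EVENT_CATEGORIES:
        pieces[f"freq_{cat}"] = g[event_flag_col(cat)].sum().astype(float)
        pieces[f"freq_ms_{cat}"] = g[f"ms_{cat}"].sum().astype(float)

    table = pd.DataFrame(pieces)[feature_columns()]

    if participants is not None:
        missing = sorted(set(participants) - set(table.index))
        if missing:
            logger.warning(
                "%d participant(s) have no retained day in the window; "
                "emitting policy-filled rows: %s", len(missing), missing[:5]
            )
        table = table.reindex(sorted(participants)).fillna(0.0)
    table.index.name = "participant_id"
    return table


def encode_baseline(baselines: pd.DataFrame) -> pd.DataFrame:
    """Encode the 7 baseline predictors: binaries as 0/1, the lifetime NSSI
    frequency band as ordinal 0..3."""
    if baselines["participant_id"].duplicated().any():
        dup = baselines.loc[
            baselines["participant_id"].duplicated(), "participant_id"
        ].iloc[0]
        raise ValueError(f"duplicate participant_id: {dup}")
    out = baselines.set_index("participant_id")[list(BASELINE_PREDICTORS)].copy()
    codebook = {band: i for i, band in enumerate(NSSI_BANDS)}
    unknown = set(out["nssi_freq_band"]) - set(codebook)
    if unknown:
        raise ValueError(f"unknown nssi_freq_band label: {sorted(unknown)[0]!r}")
    out["nssi_freq_band"] = out["nssi_freq_band"].map(codebook)
    out = out.astype(float).sort_index()
    out.index.name = "participant_id"
    return out
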
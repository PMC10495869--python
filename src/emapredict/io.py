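"""Reading, validation and day-level aggregation of EMA and baseline tables.

Missingness in this protocol occurs at the survey level, never the item
level, and is handled without imputation: if any expected prompt of a day
is missing, that whole day is excluded from the participant's daily series
(the stricter reading; ``require_both_prompts=False`` keeps days with a
single available prompt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    BASELINE_CSV_COLUMNS,
    BASELINE_PREDICTORS,
    EMA_CSV_COLUMNS,
    EVENT_CATEGORIES,
    MOOD_ITEMS,
    MOOD_MAX,
    MOOD_MIN,
    NSSI_BANDS,
    OUTCOME_COLUMNS,
    PROMPT_SLOTS,
    WORRY_MAX,
    WORRY_MIN,
    event_flag_col,
)


class SchemaError(ValueError):
    """A file or table violates the documented EMA/baseline schema."""


@dataclass
class EmaDataset:
    """A validated long-format EMA survey table plus its schedule."""

    surveys: pd.DataFrame
    n_days: int = 25
    prompts_per_day: int = 2

    @property
    def participants(self) -> list[str]:
        return sorted(self.surveys["participant_id"].unique())

    def __len__(self) -> int:
        return len(self.surveys)


def _parse_events(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split(";")


def validate_surveys(df: pd.DataFrame, n_days: int = 25) -> pd.DataFrame:
    """Validate a long survey table; raises SchemaError naming row/column."""
    missing = set(EMA_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    df = df[list(EMA_CSV_COLUMNS)].copy()
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    bad_day = (df["day"] < 1) | (df["day"] > n_days)
    if bad_day.any():
        row = int(df.index[bad_day][0])
        raise SchemaError(f"row {row}: column 'day' outside 1..{n_days}")
    bad_slot = ~df["slot"].isin(PROMPT_SLOTS)
    if bad_slot.any():
        row = int(df.index[bad_slot][0])
        raise SchemaError(f"row {row}: column 'slot' not in {PROMPT_SLOTS}")
    for col in MOOD_ITEMS:
        vals = pd.to_numeric(df[col], errors="raise")
        bad = (vals < MOOD_MIN) | (vals > MOOD_MAX) | (vals != vals.round())
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"row {row}: column '{col}' must be an integer in "
                f"{MOOD_MIN}..{MOOD_MAX}"
            )
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["participant_id", "day", "slot"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["participant_id", "day", "slot"]].tolist()
        raise SchemaError(f"duplicate (participant, day, slot) key: {key}")
    df["worry"] = pd.to_numeric(
        df["worry"].replace("", pd.NA), errors="raise"
    ).astype("Int64")
    for row, (ev_cell, most, worry) in enumerate(
        zip(df["events"], df["most_stressful"], df["worry"])
    ):
        events = _parse_events(ev_cell)
        unknown = set(events) - set(EVENT_CATEGORIES)
        if unknown:
            raise SchemaError(
                f"row {df.index[row]}: unknown event categories {sorted(unknown)}"
            )
        most = "" if pd.isna(most) else str(most)
        if events:
            if most not in events:
                raise SchemaError(
                    f"row {df.index[row]}: 'most_stressful' must be one of the "
                    "endorsed categories"
                )
            if pd.isna(worry):
                raise SchemaError(
                    f"row {df.index[row]}: 'worry' required when events endorsed"
                )
            if not WORRY_MIN <= worry <= WORRY_MAX:
                raise SchemaError(
                    f"row {df.index[row]}: column 'worry' outside "
                    f"{WORRY_MIN}..{WORRY_MAX}"
                )
        else:
            if most != "":
                raise SchemaError(
                    f"row {df.index[row]}: 'most_stressful' set without events"
                )
    df["events"] = df["events"].fillna("")
    df["most_stressful"] = df["most_stressful"].fillna("")
    return df.reset_index(drop=True)


def read_ema_long(path, n_days: int = 25, prompts_per_day: int = 2) -> EmaDataset:
    """Read and validate a long-format EMA CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False,
                     na_values=[""])
    df["events"] = df["events"].fillna("")
    df["most_stressful"] = df["most_stressful"].fillna("")
    return EmaDataset(validate_surveys(df, n_days=n_days), n_days=n_days,
                      prompts_per_day=prompts_per_day)


def write_ema_long(surveys: pd.DataFrame, path) -> None:
    surveys.to_csv(path, index=False, columns=list(EMA_CSV_COLUMNS))


def read_baseline(path) -> pd.DataFrame:
    """Read and validate the baseline predictor + outcome table."""
    df = pd.read_csv(path, dtype={"participant_id": str, "nssi_freq_band": str})
    missing = set(BASELINE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"baseline table missing columns: {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise SchemaError(f"duplicate participant_id: {dup}")
    bad_band = ~df["nssi_freq_band"].isin(NSSI_BANDS)
    if bad_band.any():
        raise SchemaError(
            f"unknown nssi_freq_band label: "
            f"{df.loc[bad_band, 'nssi_freq_band'].iloc[0]!r}"
        )
    binary = [c for c in BASELINE_PREDICTORS if c != "nssi_freq_band"]
    for col in list(binary) + list(OUTCOME_COLUMNS):
        if not df[col].isin([0, 1]).all():
            raise SchemaError(f"column '{col}' must be binary 0/1")
    return df[list(BASELINE_CSV_COLUMNS)].reset_index(drop=True)


def write_baseline(baselines: pd.DataFrame, outcomes: pd.DataFrame, path) -> None:
    """Write the single per-participant CSV (7 predictors + 4 outcomes)."""
    merged = baselines.merge(
        outcomes.drop(columns=["si_baseline"]), on="participant_id"
    )
    merged["si_baseline"] = merged["baseline_si"]
    merged.to_csv(path, index=False, columns=list(BASELINE_CSV_COLUMNS))


def compliance_rate(ds: EmaDataset) -> float:
    """Completed surveys divided by scheduled surveys."""
    n_part = len(ds.participants)
    expected = n_part * ds.n_days * ds.prompts_per_day
    if expected == 0:
        raise ValueError("compliance rate undefined: zero expected surveys")
    return len(ds.surveys) / expected


def day_aggregate(
    ds: EmaDataset, require_both_prompts: bool = True
) -> pd.DataFrame:
    """Collapse prompt-level surveys to one row per participant-day.

    A day is retained only when all expected prompts are present (or at
    least one, when ``require_both_prompts`` is False). Per retained day:
    mood items are averaged over prompts, event flags (``ev_<cat>``) are the
    union over prompts, ``event_count`` counts distinct endorsed categories,
    ``most_stressful_level`` is the maximum worry rating (0 when no event),
    and ``ms_<cat>`` flags whether the category was a "most stressful"
    selection at any of the day's prompts.
    """
    df = ds.surveys
    flags = [event_flag_col(c) for c in EVENT_CATEGORIES]
    ms_flags = [f"ms_{c}" for c in EVENT_CATEGORIES]
    cols = (["participant_id", "day"] + list(MOOD_ITEMS)
            + ["event_count", "most_stressful_level"] + flags + ms_flags)
    if df.empty:
        return pd.DataFrame(columns=cols)
    work = df.copy()
    events_lists = work["events"].map(_parse_events)
    for cat in EVENT_CATEGORIES:
        work[event_flag_col(cat)] = [int(cat in ev) for ev in events_lists]
    worry = work["worry"]
    if worry.dtype == object:
        worry = pd.to_numeric(worry.where(worry != "", np.nan), errors="coerce")
    work["_worry_num"] = worry.fillna(0).astype(int)
    most = work["most_stressful"].fillna("")
    for cat in EVENT_CATEGORIES:
        work[f"ms_{cat}"] = (most == cat).astype(int)

    g = work.groupby(["participant_id", "day"], sort=True)
    agg = {item: (item, "mean") for item in MOOD_ITEMS}
    agg.update({c: (c, "max") for c in flags + ms_flags})
    agg["most_stressful_level"] = ("_worry_num", "max")
    agg["_n_prompts"] = ("slot", "size")
    daily = g.agg(**agg).reset_index()

    required = ds.prompts_per_day if require_both_prompts else 1
    daily = daily[daily["_n_prompts"] >= required].drop(columns="_n_prompts")
    daily["event_count"] = daily[flags].sum(axis=1)
    return daily[cols].reset_index(drop=True)
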
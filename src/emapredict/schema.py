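"""Canonical column names, category tokens, and CSV schemas.

The study instrument delivers two prompts per day for 25 days. Each prompt
carries 9 raw item streams: six bipolar mood items (0-6), a stressful-event
checklist over 10 fixed categories, the single "most stressful" selection,
and a worry rating (0-6) that is only reachable when at least one event is
endorsed.
"""

from __future__ import annotations

# Six mood items (Multidimensional Mood Questionnaire style bipolar anchors),
# each scored 0-6.
MOOD_ITEMS: tuple[str, ...] = (
    "mood_tired_awake",
    "mood_content",
    "mood_agitated_calm",
    "mood_energy",
    "mood_ill_well",
    "mood_relaxed_tense",
)

# The 10 canonical stressful-event categories, in fixed tie-break order.
EVENT_CATEGORIES: tuple[str, ...] = (
    "marriage",
    "fertility",
    "economy",
    "housing",
    "medical_care",
    "family_discrimination",
    "working",
    "learning",
    "socializing",
    "other",
)

# The three event-related item streams of each prompt.
EVENT_ITEMS: tuple[str, ...] = ("events", "most_stressful", "worry")

#: All raw item streams observed at every prompt (6 mood + 3 event items).
RAW_ITEM_STREAMS: tuple[str, ...] = MOOD_ITEMS + EVENT_ITEMS

PROMPT_SLOTS: tuple[str, ...] = ("morning", "evening")

MOOD_MIN, MOOD_MAX = 0, 6
WORRY_MIN, WORRY_MAX = 0, 6

#: Bit-exact EMA long CSV header.
EMA_CSV_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "day",
    "slot",
    *MOOD_ITEMS,
    *EVENT_ITEMS,
)

# Baseline clinical/history predictors (7), one row per participant.
BASELINE_PREDICTORS: tuple[str, ...] = (
    "baseline_si",
    "nssi_freq_band",
    "lifetime_attempt",
    "psych_dx_history",
    "psych_tx_history",
    "family_attempt_history",
    "family_dx_history",
)

#: Ordinal codebook for lifetime non-suicidal self-injury frequency.
NSSI_BANDS: tuple[str, ...] = ("0", "1-10", "11-50", ">=51")

OUTCOME_COLUMNS: tuple[str, ...] = ("si_baseline", "si_1mo", "si_3mo", "si_8mo")

#: Follow-up horizons, in model order (index 0/1/2 of every beta triple).
HORIZONS: tuple[str, ...] = ("1mo", "3mo", "8mo")

BASELINE_CSV_COLUMNS: tuple[str, ...] = (
    "participant_id",
    *BASELINE_PREDICTORS,
    *OUTCOME_COLUMNS,
)

# Day-aggregated series on which the five time-series summaries are computed:
# six mood series plus daily event count and daily most-stressful worry level.
DAILY_SERIES_VARS: tuple[str, ...] = MOOD_ITEMS + ("event_count", "most_stressful_level")

EVENT_FLAG_PREFIX = "ev_"


def event_flag_col(category: str) -> str:
    return f"{EVENT_FLAG_PREFIX}{category}"
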
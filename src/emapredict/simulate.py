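"""Synthetic EMA cohort generator with a known, configurable signal structure.

The generator emulates a 25-day, twice-daily EMA protocol spanning three
waves (before / during / after the Lunar New Year period): correlated
ordinal mood items driven by a per-participant AR(1) latent, per-survey
stressful-event endorsements with wave-elevated rates for family-pressure
categories, survey-level missingness, seven baseline clinical/history
predictors, and binary suicidal-ideation outcomes at baseline and 1/3/8
months. Outcome probabilities are logistic in a standardized mood-instability
latent, a standardized event-burden latent, and baseline ideation, with
horizon-specific coefficients — so mood-dynamics signal can decay with
horizon while event-frequency signal persists.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (
    EMA_CSV_COLUMNS,
    EVENT_CATEGORIES,
    MOOD_ITEMS,
    NSSI_BANDS,
    PROMPT_SLOTS,
)

# Default per-survey endorsement probabilities per category. Work/study and
# economic stressors are commonest for a young adult cohort; marriage and
# fertility pressure are rarer outside the holiday weeks.
DEFAULT_EVENT_BASE_RATES: tuple[float, ...] = (
    0.060,  # marriage
    0.050,  # fertility
    0.080,  # economy
    0.050,  # housing
    0.050,  # medical_care
    0.060,  # family_discrimination
    0.150,  # working
    0.150,  # learning
    0.120,  # socializing
    0.100,  # other
)

# During the holiday wave, family-gathering pressure inflates marriage,
# fertility and family-discrimination event rates.
DEFAULT_WAVE2_MULTIPLIERS: tuple[float, ...] = (
    3.0,  # marriage
    3.0,  # fertility
    1.0,  # economy
    1.0,  # housing
    1.0,  # medical_care
    2.5,  # family_discrimination
    1.0,  # working
    1.0,  # learning
    1.0,  # socializing
    1.0,  # other
)

#: Categories whose endorsement counts form the event-burden outcome latent.
DEFAULT_SIGNAL_CATEGORIES: tuple[str, ...] = (
    "marriage",
    "fertility",
    "economy",
    "family_discrimination",
)

# Loadings of the six ordinal mood items on the shared affect latent.
_ITEM_LOADINGS = np.array([1.0, 0.9, 0.8, 1.0, 0.7, 0.9])
_ITEM_NOISE_SD = 0.7
_ITEM_CENTER = 3.0

# Worry-rating generation: base level + category offset + noise, clipped 0-6.
_WORRY_BASE = 2.0
_WORRY_NOISE_SD = 1.0
_WORRY_CATEGORY_OFFSET = {
    "marriage": 0.3,
    "fertility": 0.3,
    "family_discrimination": 0.4,
    "economy": 0.2,
    "working": 0.2,
    "learning": 0.2,
}

# Marginal prevalences of the binary baseline predictors and the slope of
# each on the shared vulnerability trait (roughly Table-1-like margins).
_BASELINE_PREV = {
    "lifetime_attempt": 0.05,
    "psych_dx_history": 0.35,
    "psych_tx_history": 0.30,
    "family_attempt_history": 0.20,
    "family_dx_history": 0.18,
}
_BASELINE_SLOPE = 1.0
_NSSI_BAND_PROBS = (0.61, 0.26, 0.09, 0.04)


class ConfigError(ValueError):
    """A SimConfig field is invalid; the message names the field."""


def _as_tuple(x, n: int, name: str) -> tuple[float, ...]:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)))
    if len(t) != n:
        raise ConfigError(f"{name}: expected length {n}, got {len(t)}")
    return t


@dataclass(frozen=True)
class SimConfig:
    """Study-design and signal-structure parameters of the simulated cohort.

    Defaults reproduce the study conditions: 103 participants, 25 days x 2
    prompts, ~5.5% survey-level missingness (94.5% compliance), wave
    boundaries after days 8 and 17, holiday-elevated marriage/fertility/
    family-discrimination event rates, decaying mood-effect and persistent
    event-effect outcome coefficients.
    """

    n_participants: int = 103
    n_days: int = 25
    prompts_per_day: int = 2
    wave_boundaries: tuple[int, int] = (8, 17)
    missing_rate: float = 0.055
    mood_ar_coef: float = 0.6
    mood_noise_sd: float = 0.8
    mood_noise_heterogeneity: float = 0.4
    event_base_rates: tuple[float, ...] = DEFAULT_EVENT_BASE_RATES
    wave2_multipliers: tuple[float, ...] = DEFAULT_WAVE2_MULTIPLIERS
    event_rate_heterogeneity: float = 0.15
    signal_categories: tuple[str, ...] = DEFAULT_SIGNAL_CATEGORIES
    outcome_intercepts: tuple[float, float, float, float] = (-1.77, -2.64, -1.82, -1.59)
    beta_mood: tuple[float, float, float] = (2.4, 1.0, 0.2)
    beta_event: tuple[float, float, float] = (2.6, 2.6, 2.6)
    beta_baseline_si: tuple[float, float, float] = (0.8, 0.6, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants: must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days: must be >= 1")
        if self.prompts_per_day < 1:
            raise ConfigError("prompts_per_day: must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate: must be in [0, 1]")
        if not 0.0 <= self.mood_ar_coef < 1.0:
            raise ConfigError("mood_ar_coef: must be in [0, 1)")
        if self.mood_noise_sd <= 0:
            raise ConfigError("mood_noise_sd: must be positive")
        b1, b2 = self.wave_boundaries
        if not (1 <= b1 < b2 < self.n_days):
            raise ConfigError(
                "wave_boundaries: must be strictly increasing and inside 1..n_days"
            )
        rates = _as_tuple(self.event_base_rates, 10, "event_base_rates")
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("event_base_rates: probabilities must be in [0, 1]")
        object.__setattr__(self, "event_base_rates", rates)
        mults = _as_tuple(self.wave2_multipliers, 10, "wave2_multipliers")
        if any(m < 0 for m in mults):
            raise ConfigError("wave2_multipliers: must be nonnegative")
        object.__setattr__(self, "wave2_multipliers", mults)
        unknown = set(self.signal_categories) - set(EVENT_CATEGORIES)
        if unknown:
            raise ConfigError(f"signal_categories: unknown categories {sorted(unknown)}")
        object.__setattr__(
            self, "outcome_intercepts",
            _as_tuple(self.outcome_intercepts, 4, "outcome_intercepts"))
        for name in ("beta_mood", "beta_event", "beta_baseline_si"):
            object.__setattr__(self, name, _as_tuple(getattr(self, name), 3, name))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def wave_days(self) -> tuple[range, range, range]:
        b1, b2 = self.wave_boundaries
        return (range(1, b1 + 1), range(b1 + 1, b2 + 1), range(b2 + 1, self.n_days + 1))


def null_config(**kw) -> SimConfig:
    """A configuration with no feature-outcome association of any kind."""
    base = dict(
        beta_mood=(0.0, 0.0, 0.0),
        beta_event=(0.0, 0.0, 0.0),
        beta_baseline_si=(0.0, 0.0, 0.0),
    )
    base.update(kw)
    return SimConfig(**base)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(surveys, baselines, outcomes)``: the long-format survey table
    (post-missingness), the baseline predictor table, and the outcome label
    table. Deterministic given ``config`` (which includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    P, D, S = config.n_participants, config.n_days, config.prompts_per_day
    T = D * S
    n_cat = len(EVENT_CATEGORIES)
    pids = np.array([f"p{i + 1:04d}" for i in range(P)])

    # --- latent mood: per-participant AR(1) across prompts -----------------
    noise_sd = config.mood_noise_sd * np.exp(
        config.mood_noise_heterogeneity * rng.standard_normal(P)
        - config.mood_noise_heterogeneity**2 / 2
    )
    ar = config.mood_ar_coef
    innov = rng.standard_normal((P, T)) * noise_sd[:, None]
    latent = np.empty((P, T))
    latent[:, 0] = innov[:, 0] / np.sqrt(1.0 - ar**2)  # stationary start
    for t in range(1, T):
        latent[:, t] = ar * latent[:, t - 1] + innov[:, t]

    # ordinal items: clip(round(center + loading * latent + noise), 0, 6)
    item_noise = rng.standard_normal((P, T, 6)) * _ITEM_NOISE_SD
    mood = _ITEM_CENTER + latent[:, :, None] * _ITEM_LOADINGS + item_noise
    mood = np.clip(np.rint(mood), 0, 6).astype(int)

    # --- stressful events --------------------------------------------------
    day_of_prompt = np.repeat(np.arange(1, D + 1), S)  # length T
    b1, b2 = config.wave_boundaries
    in_wave2 = (day_of_prompt > b1) & (day_of_prompt <= b2)
    rates = np.tile(np.asarray(config.event_base_rates), (T, 1))  # (T, n_cat)
    rates[in_wave2] *= np.asarray(config.wave2_multipliers)
    frailty = rng.lognormal(
        mean=-config.event_rate_heterogeneity**2 / 2,
        sigma=config.event_rate_heterogeneity,
        size=P,
    )
    prob = np.clip(rates[None, :, :] * frailty[:, None, None], 0.0, 1.0)
    endorsed = rng.random((P, T, n_cat)) < prob  # (P, T, n_cat)

    # "most stressful": endorsed category with the highest severity draw,
    # ties impossible a.s.; unendorsed categories masked out.
    severity = rng.standard_normal((P, T, n_cat))
    severity = np.where(endorsed, severity, -np.inf)
    most_idx = severity.argmax(axis=2)  # valid only where any endorsed
    any_event = endorsed.any(axis=2)

    worry_offsets = np.array(
        [_WORRY_CATEGORY_OFFSET.get(c, 0.0) for c in EVENT_CATEGORIES]
    )
    worry_raw = (
        _WORRY_BASE
        + worry_offsets[most_idx]
        + rng.standard_normal((P, T)) * _WORRY_NOISE_SD
    )
    worry = np.clip(np.rint(worry_raw), 0, 6).astype(int)

    # --- outcome latents (computed pre-missingness) ------------------------
    daily_latent = latent.reshape(P, D, S).mean(axis=2)
    instability = np.abs(np.diff(daily_latent, axis=1)).mean(axis=1) if D > 1 else np.zeros(P)
    z_mood = _standardize(instability)

    # event burden: per signal category, the number of DAYS with the category
    # endorsed (the same counting unit as the cumulative frequency features),
    # each standardized so rare categories (e.g. fertility) carry as much
    # outcome signal as common ones.
    sig_idx = [EVENT_CATEGORIES.index(c) for c in config.signal_categories]
    day_endorsed = endorsed.reshape(P, D, S, n_cat).any(axis=2)  # (P, D, n_cat)
    per_cat = day_endorsed[:, :, sig_idx].sum(axis=1).astype(float)  # (P, n_sig)
    z_event = _standardize(
        np.column_stack([_standardize(per_cat[:, j])
                         for j in range(per_cat.shape[1])]).sum(axis=1)
    )

    # --- baseline predictors and outcomes ----------------------------------
    vuln = rng.standard_normal(P)
    baselines = {"participant_id": pids}
    i0, i1, i3, i8 = config.outcome_intercepts
    baseline_si = (rng.random(P) < _sigmoid(i0 + vuln)).astype(int)
    baselines["baseline_si"] = baseline_si
    band_z = vuln + rng.standard_normal(P) * 0.8
    cuts = np.quantile(band_z, np.cumsum(_NSSI_BAND_PROBS[:-1]))
    band_code = np.searchsorted(cuts, band_z, side="right")
    baselines["nssi_freq_band"] = np.array(NSSI_BANDS)[band_code]
    for name, prev in _BASELINE_PREV.items():
        logit0 = np.log(prev / (1 - prev)) - _BASELINE_SLOPE**2 / 2
        baselines[name] = (
            rng.random(P) < _sigmoid(logit0 + _BASELINE_SLOPE * vuln)
        ).astype(int)
    baseline_df = pd.DataFrame(baselines)

    outcome = {"participant_id": pids, "si_baseline": baseline_si}
    for h, (name, icpt) in enumerate(
        zip(("si_1mo", "si_3mo", "si_8mo"), (i1, i3, i8))
    ):
        logit = (
            icpt
            + config.beta_mood[h] * z_mood
            + config.beta_event[h] * z_event
            + config.beta_baseline_si[h] * baseline_si
        )
        outcome[name] = (rng.random(P) < _sigmoid(logit)).astype(int)
    outcome_df = pd.DataFrame(outcome)

    # --- assemble the long survey table ------------------------------------
    slots = np.tile(np.array(PROMPT_SLOTS[:S]), D)
    cat_arr = np.array(EVENT_CATEGORIES)
    flat_endorsed = endorsed.reshape(P * T, n_cat)
    events_str = np.array(
        [";".join(cat_arr[row]) for row in flat_endorsed], dtype=object
    )
    most_str = np.where(
        any_event.reshape(-1), cat_arr[most_idx.reshape(-1)], ""
    ).astype(object)
    worry_col = np.where(any_event.reshape(-1), worry.reshape(-1).astype(object), pd.NA)

    surveys = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, T),
            "day": np.tile(day_of_prompt, P),
            "slot": np.tile(slots, P),
            **{
                item: mood[:, :, j].reshape(-1)
                for j, item in enumerate(MOOD_ITEMS)
            },
            "events": events_str,
            "most_stressful": most_str,
            "worry": worry_col,
        },
        columns=list(EMA_CSV_COLUMNS),
    )
    surveys["worry"] = surveys["worry"].astype("Int64")

    surveys = apply_missingness(
        surveys, config.missing_rate, seed=rng.integers(2**31)
    )
    return surveys, baseline_df, outcome_df


def apply_missingness(
    surveys: pd.DataFrame, missing_rate: float, seed: int
) -> pd.DataFrame:
    """Drop whole surveys independently with probability ``missing_rate``.

    Missingness is MCAR at the survey level, never at the item level.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigError("missing_rate: must be in [0, 1]")
    if missing_rate == 0.0:
        return surveys.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(surveys)) >= missing_rate
    return surveys.loc[keep].reset_index(drop=True)
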
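# Methods

## Study design being emulated

A 25-day EMA protocol: two prompts per day (morning, evening), each
carrying nine raw item streams — six bipolar mood items scored 0–6, a
stressful-event checklist over ten fixed categories (marriage, fertility,
economy, housing, medical care, family discrimination, working, learning,
socializing, other), the single "most stressful" selection, and a worry
rating (0–6) reachable only when at least one event is endorsed.
Missingness occurs at the survey level, never the item level; compliance is
~94.5%. The window spans three waves — before, during and after the Lunar
New Year period (default day blocks 1–8 / 9–17 / 18–25; the calendar
boundaries are a configurable convention, as no canonical split exists).
Outcomes are binary suicidal-ideation indicators (PHQ-9 item 9 ≥ 1) at
baseline and 1, 3 and 8 months.

## Synthetic cohort generator

The generator produces cohorts with this schema and a *known* signal
structure, so that every downstream claim is testable.

**Mood.** Each participant carries a latent affect process following an
AR(1) across prompts, `m_t = φ m_{t−1} + ε_t`, `ε_t ~ N(0, σ_p²)`, started
from its stationary distribution. Item j is
`clip(round(3 + λ_j m_t + N(0, 0.7²)), 0, 6)` with fixed loadings
λ = (1.0, 0.9, 0.8, 1.0, 0.7, 0.9) — correlated ordinal items without
claiming any particular factor structure. The innovation scale σ_p varies
across participants (log-normal, scale parameter `mood_noise_heterogeneity`
= 0.4), making mood instability a stable person-level trait that features
can recover.

**Events.** Category c is endorsed at each survey independently with
probability `base_rate_c × wave2_multiplier_c (during wave 2) × frailty_p`,
with a mild log-normal person frailty (σ = 0.15). Default base rates put
work/study/social stressors at 0.12–0.15 per survey and family-pressure
categories at 0.05–0.08; during the holiday wave, marriage (×3), fertility
(×3) and family discrimination (×2.5) are elevated. The "most stressful"
selection is the endorsed category with the highest independent severity
draw (ties broken by fixed category order); the worry rating is a base
level plus a small category offset plus noise, clipped to 0–6.

**Outcomes.** Two standardized person-level latents drive risk:

- *mood instability* — the mean absolute day-to-day change of the latent
  affect series;
- *event burden* — the sum over the four signal categories (marriage,
  fertility, economy, family discrimination) of the standardized number of
  days the category was endorsed. Day-level counting matches the
  feature definition; per-category standardization gives rare categories
  equal weight, so no single aggregate (e.g. the total daily event count)
  is a sufficient proxy.

The outcome at horizon h is Bernoulli with
`logit p = α_h + β_mood[h]·z_mood + β_event[h]·z_event + β_si[h]·SI_baseline`.
Defaults: β_mood = (2.4, 1.0, 0.2) — decaying with horizon; β_event =
(2.6, 2.6, 2.6) — persistent; β_si = (0.8, 0.6, 0.5). Effect sizes were
calibrated by simulation so that the *learned* cross-validated AUC of the
default pipeline sits near 0.8 at realistic cohort sizes (a logistic effect
of 2.6 on a standardized latent corresponds to an oracle AUC ≈ 0.88, of
which the pipeline recovers most). Intercepts α = (−1.77, −2.64, −1.82,
−1.59) were solved by large-n simulation to give prevalences of
18.4 / 24.8 / 29.4 / 31.1% at baseline / 1 / 3 / 8 months. Baseline
predictors derive from a shared vulnerability trait; baseline ideation is
`logit⁻¹(α_0 + v_p)`.

**Missingness** is MCAR at the whole-survey level with default rate 0.055.

**What the generator does not emulate:** demographic margins, MNAR
missingness (e.g. symptom-driven dropout), time-of-day effects, within-day
event/mood feedback, and measurement reactivity. Passing tests show the
pipeline recovers known structure under these idealized conditions; they do
not certify performance on real cohorts.

## Feature extraction

Features are computed on **day-level** series (the two prompts averaged;
event flags unioned; worry maximized), because the missingness rule is
day-based; a prompt-level mode is retained behind `require_both_prompts`.
The five summaries per series are mean, sample SD (n−1), the OLS slope on
the **calendar day index** (gaps from dropped days preserved), the maximum
absolute successive difference, and PAC. Successive differences are taken
between adjacent *retained* days by default
(`calendar_adjacent_only=False`).

**PAC threshold.** PAC has no canonical threshold; it is operationalized
per series as the 90th percentile (linear interpolation) of absolute
successive differences pooled across participants. Inside cross-validation
the thresholds are fitted on training participants only. A series with no
positive pooled differences falls back to τ = 1, making PAC identically 0.

**Degenerate windows.** A participant with fewer than two retained days in
a window gets SD/slope/max-change/PAC of 0 (mean is the single value, or 0
with no days), keeping the 60-column contract; a warning is logged. The
frequency features count retained days with the category endorsed /
selected as most stressful (days, not prompts, as the counting unit).

## Modeling and evaluation

LightGBM classifiers with fixed a-priori hyperparameters chosen for
cohorts of ~100–1000 participants and ~60 features: 300 trees, learning
rate 0.05, 7 leaves, `min_child_samples` 20, 90% row / 80% column
subsampling, and `max_bin` 15. Coarse binning suits features that are
counts and bounded scales, and it equalizes split opportunities across
feature cardinalities — otherwise split-count importance is biased toward
high-cardinality continuous features. A random-search tuner (25 candidates,
3-fold inner CV, ties broken toward fewer trees then fewer leaves) is
available but off by default; with fixed defaults the cross-validation
estimate is not confounded by per-fold tuning noise.

Evaluation is stratified k-fold (default 5 × 3 repetitions; 10 × 3 and
LOOCV variants). Per fold: PAC thresholds from the training portion;
model fit on the training portion; the classification threshold maximizes
Youden's J on **out-of-fold training predictions** (3-fold within the
training portion) — in-sample scores are overfit toward 0/1 and would
misplace the cut-point relative to the shrunken held-out probabilities.
A fixed-0.5 threshold mode exists. PPV is reported as missing when no case
is predicted positive. LOOCV pools all held-out predictions before
computing a single metric set, since per-case AUC is undefined. Summaries
are mean ± 1.96·SE over fold values; fold values are not independent, and
this caveat travels in each experiment's metadata rather than being
"corrected".

**Importance** is the split-node count per feature, scaled so the
most-used feature scores 100 (unsplit features score 0; score =
100·count/max, so ranking equals raw-count ranking). Because split
allocation among correlated features is noisy in a single ensemble,
`averaged_split_importance` averages counts over refits that differ only in
subsampling seed; analyses that compare rankings across horizons or
configurations additionally pool counts over replicate cohorts.

## Experiments

All designs within one experiment share fold assignments (verifiable by
the logged fold hash), so cross-design comparisons are paired by fold.
Metric differences use two-sided Welch t tests (a paired mode exists) with
Benjamini–Hochberg adjustment applied within each experiment-horizon
family. The day-overlay curve evaluates windows days 1..k for k = 1..25
and reports the smallest k whose mean AUC exceeds the conventional 0.70
"acceptable accuracy" level (a named, configurable constant).

## Problem sizes and numerical conventions

The test suite exercises the calibration properties at the sizes the
design states: null calibration on twenty 1000-participant cohorts (mean
CV AUC must lie in [0.45, 0.55]); signal recovery on three 400-participant
event-driven cohorts (mean CV AUC > 0.75; the four outcome-driving
frequency features in the importance top 10 on pooled split counts); and
horizon/wave pattern recovery on 400-participant cohorts. Oracle
equivalence checks run the summaries against brute-force recomputation on
1000 random series at 1e-10 relative tolerance, AUC against pairwise
enumeration, and BH against the textbook step-up rule. All randomness
flows from explicit integer seeds; reruns are bit-identical.

## Known limitations

- Split-count importance measures how often a feature is *used*, not its
  marginal effect; correlated features share and trade splits, so ranks
  of near-duplicates (a category's endorsement frequency vs its
  most-stressful frequency) are individually unstable on small cohorts.
- Wald binomial intervals are used for prevalences to match the reporting
  convention they reproduce; they are known to undercover near 0 and 1.
- The Youden threshold targets balanced sensitivity/specificity; with
  ~25% outcome prevalence this caps PPV well below the sensitivity level.
- Fold-level t tests treat dependent CV metrics as samples; p-values are
  descriptive annotations of the comparison, not exact error rates.
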
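# emapredict

Prediction of short- and longer-term **suicidal ideation** from
**ecological momentary assessment (EMA)** data: twice-daily mood ratings and
stressful-event reports collected over a 25-day window spanning the three
waves of the Lunar New Year period (before / during / after), in a cohort of
sexual and gender minority young adults.

The package is for researchers working with intensive longitudinal data who
want a tested, fully reproducible pipeline for this class of analysis:
because the original cohort data cannot be shared, every stage runs on a
**synthetic cohort generator** with a known, configurable signal structure,
so the whole pipeline — feature extraction, model evaluation, experiment
designs — is verifiable end to end.

## What it computes

**Features (60 per participant per window).** Surveys are aggregated to
days (a day with any missing prompt is excluded; no imputation). For each
of eight daily series — six mood items (0–6), the daily count of distinct
stressful-event categories, and the daily most-stressful worry level —
five time-series summaries are computed:

- mean, sample SD (`n−1`), OLS **slope** on the calendar day index,
- **maximum change** `max|x(t+1) − x(t)|` over successive retained days,
- **PAC** (probability of acute change): the fraction of successive changes
  `≥ τ`, with `τ` the 90th percentile of pooled absolute successive changes
  across training participants.

That is 5 × 8 = 40 summaries, plus the cumulative person-specific frequency
of each of the 10 event categories (days endorsed, and days selected as
"most stressful"): 20 counts. Seven baseline clinical/history predictors
(baseline ideation, NSSI frequency band, lifetime attempt, psychiatric
diagnosis/treatment history, family attempt/diagnosis history) can be
appended.

**Models and evaluation.** LightGBM gradient-boosted trees, evaluated under
stratified 5-fold cross-validation with 3 repetitions (10-fold and
leave-one-out variants included), reporting AUC, sensitivity, specificity
and PPV per fold with normal-approximation 95% CIs. Classification
cut-points maximize Youden's J on out-of-fold training predictions. PAC
thresholds are fitted on training folds only. Importance is the split-node
count per feature, scaled 0–100.

**Experiments.** Three designs, each on identical fold assignments with
Welch t tests and Benjamini–Hochberg FDR adjustment: (1) baseline vs EMA vs
baseline+EMA predictor sets, (2) incremental day-overlay curves (days 1..k)
with the smallest k reaching AUC > 0.70, (3) per-wave models using each
holiday wave's days only.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # writes scratch/data/
python analysis/03_compare_predictor_sets.py # writes results/compare/
```

prints (103 simulated participants, seed 20260929):

```
cohort: 103 participants, 4859 completed surveys, compliance 94.3%
si_baseline: 13.6% (95% CI 7.0-20.2%)
si_1mo: 24.3% (95% CI 16.0-32.6%)
...
=== 1mo (fold hash bbf7f14b1fce1ded) ===
  baseline           AUC 0.543 (0.469-0.617)
  ema                AUC 0.792 (0.731-0.854)
  baseline_plus_ema  AUC 0.786 (0.727-0.844)
  AUC baseline vs ema: t=-5.08, adj p=0.0002
=== 3mo ===
  baseline           AUC 0.539 ...   ema  AUC 0.737 (0.683-0.791)
=== 8mo ===
  baseline           AUC 0.450 ...   ema  AUC 0.597 (0.528-0.665)
```

Reading this: EMA dynamics alone discriminate future ideation well at one
month (mean cross-validated AUC 0.79) and the advantage decays with horizon
— exactly the signal structure the generator builds in (mood-instability
effects decay from 1 to 8 months, event-frequency effects persist). Adding
the seven baseline predictors to EMA changes little, and baseline alone is
near chance here because this simulated cohort's outcome signal flows
through the EMA latents. At this cohort size (n=103) fold-level metrics are
noisy; single-cohort results (e.g. which wave wins in
`analysis/05_wave_analysis.py`) vary between seeds, which is why the
acceptance checks below aggregate over larger or repeated cohorts.

The same stages are available as a CLI
(`emapredict simulate|featurize|evaluate|compare|day-curve|waves|report`),
e.g.:

```bash
emapredict simulate --seed 11 --n-participants 103 --out scratch/data
emapredict compare --data scratch/data --seed 11 --horizon 1mo --out results/compare_cli
```

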
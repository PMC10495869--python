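#!/usr/bin/env python
"""Extract the 60 EMA features and 7 baseline predictors from the cohort.

Reads scratch/data/, applies the day-level missingness rule (a day with any
missing prompt is excluded), fits the per-series PAC thresholds on the full
cohort, and writes the participant x feature tables under results/features/.
"""

from pathlib import Path

from emapredict.features import build_feature_table, encode_baseline, fit_pac_thresholds
from emapredict.io import day_aggregate, read_baseline, read_ema_long

data = Path("scratch/data")
out = Path("results/features")
out.mkdir(parents=True, exist_ok=True)

ds = read_ema_long(data / "ema.csv")
base = read_baseline(data / "baseline.csv")
daily = day_aggregate(ds)

thresholds = fit_pac_thresholds(daily)
table = build_feature_table(daily, pac_thresholds=thresholds,
                            participants=sorted(base["participant_id"]))
table.to_csv(out / "ema_features.csv")
encode_baseline(base).to_csv(out / "baseline_features.csv")

print(f"daily series: {len(daily)} retained participant-days")
print(f"EMA feature table: {table.shape[0]} participants x {table.shape[1]} features")
print("PAC thresholds (90th pct of pooled |successive change|):")
for var, thr in thresholds.items():
    print(f"  {var}: {thr:.3f}")
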
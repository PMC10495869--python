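#!/usr/bin/env python
"""Incremental day-overlay curve: how many EMA days are enough?

Evaluates the EMA model using only the first k days of data, k = 1..25,
on shared folds, and reports the smallest k whose mean CV AUC exceeds the
conventional 0.70 'acceptable accuracy' level. Writes results/day_curve/.
"""

import sys
from pathlib import Path

from emapredict.experiments import incremental_day_curve
from emapredict.io import day_aggregate, read_baseline, read_ema_long
from emapredict.modeling import CvScheme

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260929

data = Path("scratch/data")
out = Path("results/day_curve")
out.mkdir(parents=True, exist_ok=True)

ds = read_ema_long(data / "ema.csv")
base = read_baseline(data / "baseline.csv")
daily = day_aggregate(ds)

for horizon in ("1mo", "3mo", "8mo"):
    labels = base.set_index("participant_id")[f"si_{horizon}"].sort_index()
    curve, crossing_k, _ = incremental_day_curve(
        daily, labels, horizon, CvScheme(k=5, repetitions=3, seed=SEED))
    curve.to_csv(out / f"curve_{horizon}.csv", index=False)
    best = curve.loc[curve["mean_auc"].idxmax()]
    print(f"{horizon}: AUC range {curve['mean_auc'].min():.2f}-"
          f"{curve['mean_auc'].max():.2f}; best at k={int(best['k'])}; "
          f"first k with AUC>0.70: {crossing_k}")
print(f"wrote curves under {out}/")
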
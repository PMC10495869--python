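#!/usr/bin/env python
"""Per-wave evaluation: before, during and after the holiday period.

Features are recomputed within each wave's days only (still 60 columns),
the three wave models are evaluated on shared folds, and cross-wave metric
differences are Welch-tested with BH adjustment. Writes results/waves/.
"""

import sys
from pathlib import Path

from emapredict.experiments import wave_analysis
from emapredict.io import day_aggregate, read_baseline, read_ema_long
from emapredict.modeling import CvScheme

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260929

data = Path("scratch/data")
out = Path("results/waves")
out.mkdir(parents=True, exist_ok=True)

ds = read_ema_long(data / "ema.csv")
base = read_baseline(data / "baseline.csv")
daily = day_aggregate(ds)

for horizon in ("1mo", "3mo", "8mo"):
    labels = base.set_index("participant_id")[f"si_{horizon}"].sort_index()
    res = wave_analysis(daily, labels, horizon,
                        CvScheme(k=5, repetitions=3, seed=SEED),
                        wave_boundaries=(8, 17))
    print(f"=== {horizon} ===")
    for wave, dist in res.results.items():
        s = dist.summary().set_index("metric")
        print(f"  {wave}: AUC {s.loc['auc', 'mean']:.3f} "
              f"({s.loc['auc', 'ci_lower']:.3f}-{s.loc['auc', 'ci_upper']:.3f})")
    hdir = out / horizon
    hdir.mkdir(exist_ok=True)
    for wave, dist in res.results.items():
        dist.folds.to_csv(hdir / f"metrics_{wave}.csv", index=False)
    res.tests.to_csv(hdir / "tests.csv", index=False)
print(f"wrote tables under {out}/")
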
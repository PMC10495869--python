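#!/usr/bin/env python
"""Split-count feature importance, full window and per wave, per horizon.

Importance is the number of times a feature is used as a split node,
averaged over ten refits differing only in subsampling seed, rescaled so
the top feature scores 100. Writes ranked tables under
results/importance/ and prints each horizon's top 10.
"""

import sys
from pathlib import Path

from emapredict.experiments import wave_days
from emapredict.features import build_feature_table, fit_pac_thresholds
from emapredict.io import day_aggregate, read_baseline, read_ema_long
from emapredict.modeling import averaged_split_importance

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260929

data = Path("scratch/data")
out = Path("results/importance")
out.mkdir(parents=True, exist_ok=True)

ds = read_ema_long(data / "ema.csv")
base = read_baseline(data / "baseline.csv")
daily = day_aggregate(ds)
pids = sorted(base["participant_id"])

windows = {"all25": None}
windows.update(wave_days((8, 17), 25))

for horizon in ("1mo", "3mo", "8mo"):
    labels = base.set_index("participant_id")[f"si_{horizon}"].sort_index()
    for wname, window in windows.items():
        table = build_feature_table(
            daily, window, fit_pac_thresholds(daily, window),
            participants=pids)
        imp = averaged_split_importance(table, labels.to_numpy(), seed=SEED)
        imp.to_csv(out / f"importance_{horizon}_{wname}.csv", index=False)
        if wname == "all25":
            top = ", ".join(
                f"{r.feature} ({r.score:.0f})" for r in imp.head(10).itertuples())
            print(f"{horizon} top 10: {top}")
print(f"wrote tables under {out}/")
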
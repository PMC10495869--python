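#!/usr/bin/env python
"""Compare baseline, EMA, and baseline+EMA predictor sets at each horizon.

For each follow-up horizon (1/3/8 months) the three designs are evaluated
on identical 5-fold x 3-repetition stratified splits; fold-level metric
differences are tested with Welch t tests and BH-adjusted within each
horizon. Writes per-horizon metric, summary and test tables under
results/compare/.
"""

import sys
from pathlib import Path

from emapredict.experiments import compare_predictor_sets
from emapredict.features import encode_baseline
from emapredict.io import day_aggregate, read_baseline, read_ema_long
from emapredict.modeling import CvScheme

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260929

data = Path("scratch/data")
out = Path("results/compare")
out.mkdir(parents=True, exist_ok=True)

ds = read_ema_long(data / "ema.csv")
base = read_baseline(data / "baseline.csv")
daily = day_aggregate(ds)
base_enc = encode_baseline(base)

for horizon in ("1mo", "3mo", "8mo"):
    labels = base.set_index("participant_id")[f"si_{horizon}"].sort_index()
    res = compare_predictor_sets(daily, base_enc, labels, horizon,
                                 CvScheme(k=5, repetitions=3, seed=SEED))
    print(f"\n=== {horizon} (fold hash {res.metadata['fold_hash']}) ===")
    for design, dist in res.results.items():
        s = dist.summary().set_index("metric")
        print(f"  {design:18s} AUC {s.loc['auc', 'mean']:.3f} "
              f"({s.loc['auc', 'ci_lower']:.3f}-{s.loc['auc', 'ci_upper']:.3f})")
    sig = res.tests[(res.tests["metric"] == "auc")
                    & (res.tests["p_adjusted"] < 0.05)]
    for _, row in sig.iterrows():
        print(f"  AUC {row.design_a} vs {row.design_b}: t={row.t:.2f}, "
              f"adj p={row.p_adjusted:.4f}")
    hdir = out / horizon
    hdir.mkdir(exist_ok=True)
    for design, dist in res.results.items():
        dist.folds.to_csv(hdir / f"metrics_{design}.csv", index=False)
        dist.summary().to_csv(hdir / f"summary_{design}.csv", index=False)
    res.tests.to_csv(hdir / "tests.csv", index=False)
print(f"\nwrote tables under {out}/")
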
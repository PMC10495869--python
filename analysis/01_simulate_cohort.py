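#!/usr/bin/env python
"""Simulate the default study cohort and write its raw tables.

Generates a 103-participant cohort under the default conditions (25 days x
2 prompts, ~5.5% survey-level missingness, three holiday waves with
elevated marriage/fertility/family-discrimination event rates) and writes
ema.csv + baseline.csv under scratch/data/, printing compliance and
outcome prevalences.
"""

import sys
from pathlib import Path

from emapredict.io import EmaDataset, compliance_rate, write_baseline, write_ema_long
from emapredict.modeling import prevalence_with_ci
from emapredict.simulate import SimConfig, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260929

out = Path("scratch/data")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=SEED)
surveys, baselines, outcomes = generate_cohort(cfg)
write_ema_long(surveys, out / "ema.csv")
write_baseline(baselines, outcomes, out / "baseline.csv")

ds = EmaDataset(surveys, cfg.n_days, cfg.prompts_per_day)
print(f"cohort: {cfg.n_participants} participants, {len(surveys)} completed "
      f"surveys, compliance {compliance_rate(ds):.1%}")
for col in ("si_baseline", "si_1mo", "si_3mo", "si_8mo"):
    p, lo, hi = prevalence_with_ci(outcomes[col].to_numpy())
    print(f"{col}: {p:.1f}% (95% CI {lo:.1f}-{hi:.1f}%)")
print(f"wrote {out}/ema.csv and {out}/baseline.csv")
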
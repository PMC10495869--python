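import pytest

from emapredict.io import EmaDataset, day_aggregate
from emapredict.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant simulated cohort with default signal structure."""
    cfg = SimConfig(n_participants=40, seed=123)
    surveys, baselines, outcomes = generate_cohort(cfg)
    return cfg, surveys, baselines, outcomes


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    cfg, surveys, _, _ = small_cohort
    return day_aggregate(EmaDataset(surveys, cfg.n_days, cfg.prompts_per_day))


@pytest.fixture(scope="session")
def complete_cohort():
    """10 participants, no missingness: every scheduled survey present."""
    cfg = SimConfig(n_participants=10, missing_rate=0.0, seed=7)
    surveys, baselines, outcomes = generate_cohort(cfg)
    return cfg, surveys, baselines, outcomes
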
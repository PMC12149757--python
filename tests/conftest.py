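import numpy as np
import pandas as pd
import pytest

from advisdt import ExperimentConfig, ProfileDistribution, simulate_experiment
from advisdt.config import BlockSpec


def small_config(n_per_condition: int = 6, block_len: int = 8,
                 seed: int = 0) -> ExperimentConfig:
    """Minimal valid design: 6 blocks (2 per phase), 5 self-report queries."""
    probs = (0.9, 0.9, 0.75, 0.45, 0.9, 0.9)
    phases = ("pre-error", "pre-error", "error", "error", "post-error", "post-error")
    return ExperimentConfig(
        n_participants_per_condition=n_per_condition,
        n_trials_session1=6 * block_len,
        blocks_session2=tuple(
            BlockSpec(n_trials=block_len, p_correct_advice=p) for p in probs),
        phase_labels=phases,
        selfreport_timepoints=(1, 2, 3, 4, 6),
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_config() -> ExperimentConfig:
    return small_config()


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """One small simulated cohort shared by read-only tests."""
    return simulate_experiment(tiny_config, ProfileDistribution(), rng_seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """A default-design cohort (216 + 216 trials) at a reduced headcount."""
    cfg = ExperimentConfig(n_participants_per_condition=4)
    return simulate_experiment(cfg, ProfileDistribution(), rng_seed=5)
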
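import numpy as np
import pytest

from flysleep import (
    ActivityTable,
    SimConfig,
    make_abridged_ssd,
    make_full_ssd,
    score_sleep,
    simulate_cohort,
)


def make_table(counts, zt0=0.0, fly_ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    if fly_ids is None:
        fly_ids = [f"fly{i}" for i in range(counts.shape[0])]
    return ActivityTable(counts=counts, fly_ids=fly_ids, zt0=zt0)


@pytest.fixture(scope="session")
def full_schedule():
    return make_full_ssd()


@pytest.fixture(scope="session")
def abridged_schedule():
    return make_abridged_ssd()


@pytest.fixture(scope="session")
def small_cohort(abridged_schedule):
    """8 mechanistic flies through the abridged protocol (fast)."""
    cfg = SimConfig(n_flies=8, seed=7)
    table = simulate_cohort(cfg, abridged_schedule)
    return cfg, table, score_sleep(table)


@pytest.fixture(scope="session")
def gain_cohort(full_schedule):
    """32 flies, full protocol, gain injection with the study's morning
    and evening rebound gains (133 min at ZT1.5, 51 min at ZT9.5)."""
    cfg = SimConfig(n_flies=32, seed=42, mode="gain_injection")
    table = simulate_cohort(cfg, full_schedule)
    return cfg, table, score_sleep(table)
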
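import numpy as np
import pytest

from sanmodel import map_rate_schedule, simulate_ensemble


@pytest.fixture(scope="session")
def map_schedule():
    return map_rate_schedule()


@pytest.fixture(scope="session")
def big_map_ensemble(map_schedule):
    """Shared 10^5-lineage ensemble under the packaged rates (seeded)."""
    return simulate_ensemble(
        100_000, map_schedule, record_days=[3, 6, 11, 40], rng=20_240
    )


@pytest.fixture(scope="session")
def traj_map_ensemble(map_schedule):
    """Densely recorded ensemble for extinction-time stratification."""
    return simulate_ensemble(
        60_000,
        map_schedule,
        record_days=[11, 13, 16, 20, 25, 30, 35, 40],
        rng=77,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
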
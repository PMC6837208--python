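import numpy as np
import pytest

import ttbsearch as tb
from ttbsearch.landscape import Landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poor_landscape():
    return tb.generate_landscape((63, 63), 32, np.random.default_rng(7), seed=7)


@pytest.fixture(scope="session")
def zero_landscape():
    """Flat landscape: every cue except pay-off still operates."""
    return Landscape(payoffs=np.zeros((63, 63), dtype=int), n_peaks=1, scale_max=0, kind="custom")


@pytest.fixture(scope="session")
def zero_line():
    return Landscape(payoffs=np.zeros((1, 63), dtype=int), n_peaks=1, scale_max=0, kind="custom")


@pytest.fixture(scope="session")
def ttb_exploration_batch():
    """Small exploration-phase batch from the default 3-cue model."""
    phase = tb.PhaseConfig.preset("exploration", "poor")
    return tb.run_batch(phase, tb.AgentParams(), n_landscapes=10, trials_per_landscape=2,
                        master_seed=42)


@pytest.fixture(scope="session")
def returning_batch():
    """Exploitation-phase batch from the full returning model."""
    phase = tb.PhaseConfig.preset("exploitation", "rich")
    params = tb.AgentParams(exploitation_model="returning")
    return tb.run_batch(phase, params, n_landscapes=100, trials_per_landscape=1, master_seed=99)
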
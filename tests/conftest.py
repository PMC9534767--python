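import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def neutral_snapshot():
    """One neutral trajectory from a single 1-copy founder to 1e4 cells."""
    from ecdna_dyn import SimulationConfig, run_gillespie

    return run_gillespie(SimulationConfig(n0=1, s=1.0, n_target=10_000, seed=7))[-1]


@pytest.fixture(scope="session")
def wide_distribution():
    """A wide copy-number distribution from a positively selected population."""
    from ecdna_dyn import SimulationConfig, run_gillespie, summarize

    state = run_gillespie(SimulationConfig(n0=1, s=2.0, n_target=100_000, seed=11))[-1]
    return summarize(state).distribution
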
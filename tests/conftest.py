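import numpy as np
import pandas as pd
import pytest

from methylclass import BetaMatrix, SimulationConfig, simulate_panel


def small_config(**overrides) -> SimulationConfig:
    """A compact panel: quick to simulate, still carries all planted axes."""
    defaults = dict(n_probes=500, n_sc=16, n_ipsc=8, n_esc=8, n_x_probes=60,
                    n_informative_scpc=30, n_informative_escipsc=40,
                    n_informative_stage=20, seed=11)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_panel(small_config())


@pytest.fixture(scope="session")
def medium_panel():
    """Larger cohort for evaluation statistics (30 SC, 15+15 PC)."""
    return simulate_panel(small_config(n_probes=800, n_sc=30, n_ipsc=15,
                                       n_esc=15, n_x_probes=80, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_beta_matrix(rng, n_probes=10, n_samples=8) -> BetaMatrix:
    values = rng.uniform(0.02, 0.98, size=(n_probes, n_samples))
    return BetaMatrix(pd.DataFrame(
        values,
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=[f"S{j:03d}" for j in range(n_samples)]))
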
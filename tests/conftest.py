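import numpy as np
import pandas as pd
import pytest

from cfrank import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    """8 well-separated types, 40 markers each, noise off by default."""
    return sim.SimulationConfig(
        n_celltypes=8, n_genes=400, n_marker_genes_per_type=40,
        noise_sd=0.0, depletion_depth=0.7, seed=0,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return sim.simulate_reference(small_config, seed=1)


@pytest.fixture()
def uniform_weights(small_reference):
    k = len(small_reference.cell_types)
    return pd.Series(np.full(k, 1.0 / k), index=small_reference.cell_types)


@pytest.fixture()
def onehot_weights(small_reference):
    w = pd.Series(0.0, index=small_reference.cell_types)
    w.iloc[0] = 1.0
    return w
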
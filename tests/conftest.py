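import numpy as np
import pytest

from raremix.model import RareCellMixtureModel
from raremix.simulate import (SimulationConfig, simulate_candidate_detector,
                              simulate_pc_data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def default_simulation():
    """One dataset under the default study conditions, with candidates."""
    cfg = SimulationConfig(seed=3)
    data, abundant, truth = simulate_pc_data(cfg)
    cand = simulate_candidate_detector(truth, noise_rate=1.0, seed=4)
    return cfg, data, abundant, truth, cand


@pytest.fixture(scope="session")
def fitted_results(default_simulation):
    """A short but converged fit of the default simulated dataset."""
    _, data, abundant, truth, cand = default_simulation
    model = RareCellMixtureModel(data.subset(cand.indices), cand.init_labels,
                                 abundant)
    return model.fit(n_iter=600, n_burn=300, seed=11)
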
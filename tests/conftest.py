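import numpy as np
import pandas as pd
import pytest

from proteokinetics import TimecourseModel, default_design
from proteokinetics.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment (seed 1) shared across tests."""
    cfg = SimulationConfig(seed=1)
    intensities, truth, ann = simulate(cfg)
    return cfg, intensities, truth, ann


@pytest.fixture(scope="session")
def default_fit(default_sim):
    cfg, intensities, truth, ann = default_sim
    res = TimecourseModel(intensities, cfg.design, ann).fit()
    return cfg, truth, res


def random_ratio_matrix(rng, n_proteins, n_samples, ids=None):
    """Positive ratio matrix with lognormal entries (test helper)."""
    ids = ids or [f"Q{i:02d}" for i in range(n_proteins)]
    vals = np.exp(rng.normal(0.0, 0.4, size=(n_proteins, n_samples)))
    return pd.DataFrame(
        vals, index=ids, columns=[f"s{j}" for j in range(n_samples)]
    )
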
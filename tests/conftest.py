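import numpy as np
import pytest

from firekrige import SimulationTruth, generate_design, simulate_field


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def smooth_obs(design):
    """Strongly autocorrelated noiseless field on the default design."""
    truth = SimulationTruth(beta=(5.0, 0.2, 0.0), sigma2=1.0, phi=4.0, tau2_rel=0.0)
    return simulate_field(design, truth, seed=2)


@pytest.fixture(scope="session")
def row9():
    """A single 9-core row at 2 m spacing — the cheapest valid design."""
    return generate_design(spacings=(2.0,) * 8, n_rows=1)


@pytest.fixture(autouse=True)
def _quiet_numerics():
    """Degenerate-cell warnings are expected in stress configurations."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(points)
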
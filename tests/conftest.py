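import numpy as np
import pytest

from strucnet.connectome import ConnectivityMatrix
from strucnet.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def triangle_matrix():
    """Uniform triangle, all weights 0.5."""
    w = np.full((3, 3), 0.5)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w)


@pytest.fixture
def path3_matrix():
    """3-node path 0-1-2 with unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    return ConnectivityMatrix(w)


def small_cohort_config(**overrides) -> SyntheticConfig:
    """Reduced-scale cohort for fast statistical tests."""
    base = dict(
        n_nodes=20, n_hv=8, n_ms=10, edge_density=0.5,
        n_hub_nodes=3, n_edges_decreased=20, n_edges_increased=4,
        n_circuit_edges=5, seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_cohort_config())
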
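import numpy as np
import pytest

import somstab as ss


@pytest.fixture(scope="session")
def small_mixture():
    """A 2,000-cell, 10-channel labeled mixture (default panel)."""
    return ss.generate_mixture(ss.default_populations(10), 2000, seed=11)


@pytest.fixture(scope="session")
def scaled_matrix(small_mixture):
    """The small mixture arcsinh-scaled, ready for SOM training."""
    x = ss.ExpressionMatrix(
        small_mixture.matrix.values,
        small_mixture.matrix.channel_names,
        "arcsinh",
    )
    return ss.scale_channels(x)


@pytest.fixture(scope="session")
def trained_som(scaled_matrix):
    """A deterministic 4x4 SOM fit on the small mixture."""
    return ss.SOM(scaled_matrix, xdim=4, ydim=4, rlen=10, seed=5).fit()


def random_partition(n_cells: int, k: int, rng) -> ss.NodeAssignment:
    """A random assignment of n_cells to k nodes (zero distances)."""
    return ss.NodeAssignment(
        node_index=rng.integers(0, k, size=n_cells),
        distance=np.zeros(n_cells),
        k=k,
    )
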
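import numpy as np
import pytest

from sparsect import ImageGrid, ProjectionGeometry, build_system_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_system(rng):
    """8x8 grid, 10 views, 8 detectors: a small CT system with its matrix."""
    grid = ImageGrid(rng.random((8, 8)))
    geom = ProjectionGeometry.uniform(10, 8)
    A = build_system_matrix(grid, geom)
    return grid, geom, A
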
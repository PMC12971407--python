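import numpy as np
import pytest

from ecocoupling.grid import LEGEND, CategoricalGrid, Grid

CODE = {name: code for code, name in LEGEND.items()}


@pytest.fixture
def code():
    """Class-name -> legend-code mapping."""
    return CODE


@pytest.fixture
def checkerboard8():
    """8x8 two-class checkerboard (forest / grassland)."""
    rows, cols = np.indices((8, 8))
    codes = np.where((rows + cols) % 2 == 0, CODE["forest"], CODE["grassland"])
    return CategoricalGrid(codes=codes)


@pytest.fixture
def ring_grid():
    """3x3 forest ring around one grassland cell."""
    codes = np.full((3, 3), CODE["forest"])
    codes[1, 1] = CODE["grassland"]
    return CategoricalGrid(codes=codes)


@pytest.fixture
def random_landscape_factory():
    """Seeded random small landscapes over a configurable class count."""

    def make(seed: int, shape=(8, 8), n_classes=4) -> CategoricalGrid:
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, n_classes + 1, size=shape)
        return CategoricalGrid(codes=codes)

    return make


@pytest.fixture
def constant_grid():
    return Grid(values=np.full((6, 6), 2.0))
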
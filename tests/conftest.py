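import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spatentropy as se

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def unit_square():
    return se.ObservationWindow.from_vertices([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def csr_pattern(unit_square):
    """500 uniform points in the unit square, fixed seed."""
    return se.generate_csr(unit_square, 500, seed=20240901)


@pytest.fixture
def marked_csr_pattern(unit_square):
    """500 uniform points with independent equiprobable binary marks."""
    return se.generate_csr(unit_square, 500, seed=20240902,
                           mark_probs={"a": 0.5, "b": 0.5})


@pytest.fixture
def corner_pattern(unit_square):
    """The hand-worked 4-corner fixture: a's on one diagonal, b's on the other."""
    return se.PointPattern([(0, 0), (1, 1), (1, 0), (0, 1)], unit_square,
                           ["a", "a", "b", "b"])


@pytest.fixture
def small_raster():
    """5x6 binary raster with two NODATA cells, unit cells at the origin."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 2, size=(5, 6))
    mask = np.zeros((5, 6), bool)
    mask[0, 0] = mask[3, 4] = True
    return se.CategoricalRaster(values, mask)
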
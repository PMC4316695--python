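import numpy as np
import pytest

from dvfcompare import DisplacementField, GridGeometry


@pytest.fixture
def small_grid() -> GridGeometry:
    """Small anisotropic grid: cheap, but catches spacing bugs."""
    return GridGeometry(dims=(16, 14, 12), spacing=(1.5, 2.0, 2.5), origin=(-10.0, 0.0, 5.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150204)


def random_field(geom: GridGeometry, rng: np.random.Generator, scale: float = 3.0) -> DisplacementField:
    return DisplacementField(
        geometry=geom, vectors=rng.normal(0.0, scale, size=geom.dims + (3,))
    )
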
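import numpy as np
import pytest

from spectralseg.core import SpectralStack, TissueLabelMap
from spectralseg.phantom import GridSpec, PhantomGeometry, SpectralModel, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_geometry():
    return PhantomGeometry()


@pytest.fixture
def default_grid():
    return GridSpec()


@pytest.fixture
def default_spectral():
    return SpectralModel()


#: coarse grid that still fits the default head: 32x32x16 voxels at 6x6x8 mm
TINY_GRID = GridSpec(shape=(32, 32, 16), spacing=(6.0, 6.0, 8.0))


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Four small phantom cases on disk plus their manifest."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(4, out, grid=TINY_GRID, seed=11)
    return manifest


@pytest.fixture(scope="session")
def tiny_cases(tiny_cohort):
    return tiny_cohort.load_all()


def random_stack(rng, shape=(8, 8, 4), spacing=(1.0, 1.0, 1.0),
                 levels=(50, 70, 120)):
    return SpectralStack({lv: rng.normal(50, 10, size=shape).astype(np.float32)
                          for lv in levels}, spacing)


def random_labels(rng, shape=(8, 8, 4), spacing=(1.0, 1.0, 1.0)):
    return TissueLabelMap(rng.integers(0, 4, size=shape).astype(np.int16), spacing)
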
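import numpy as np
import pytest

from symmorph.landmark_io import LandmarkConfiguration, SymmetryMap
from symmorph.synthetic_data import SyntheticParams, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Modest modular dataset: 60 specimens, 34-landmark face template."""
    return generate(SyntheticParams(n_specimens=60, seed=11))


@pytest.fixture(scope="session")
def replicate_dataset():
    """Dataset with 2 digitization replicates and measurement error."""
    return generate(SyntheticParams(n_specimens=40, seed=13, sigma_err=0.1,
                                    n_replicates=2))


@pytest.fixture
def toy_smap():
    """5 landmarks in 2D: two pairs + one midline landmark."""
    return SymmetryMap(pairs=[(0, 1), (2, 3)], midline=[4], reflection_axis=0)


@pytest.fixture
def toy_config(toy_smap):
    coords = np.array([
        [1.0, 2.0],    # left of pair 0
        [-1.2, 2.0],   # right of pair 0
        [0.8, -1.0],
        [-0.8, -1.0],
        [0.0, 1.0],    # midline
    ])
    return LandmarkConfiguration("toy", coords)
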
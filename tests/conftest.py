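import numpy as np
import pytest

from speleoplan.engine import BeamModel, bragg_curve
from speleoplan.pipeline import water_box


@pytest.fixture(scope="session")
def beam150():
    return BeamModel(nominal_energy=150.0)


@pytest.fixture(scope="session")
def pristine150(beam150):
    return bragg_curve(150.0, beam150.energy_sigma, beam150.depth_step)


@pytest.fixture(scope="session")
def small_water_box():
    """Coarse water slab big enough for a 150 MeV beam."""
    return water_box(100.0, 190.0, voxel=(2.0, 2.0, 1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
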
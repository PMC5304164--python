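import numpy as np
import pytest

from augerdna.decay import get_nuclide
from augerdna.nanodose import CylinderTarget
from augerdna.plasmid import PlasmidPrep


@pytest.fixture(scope="session")
def tc99m():
    return get_nuclide("99mTc")


@pytest.fixture(scope="session")
def i125():
    return get_nuclide("125I")


@pytest.fixture(scope="session")
def target():
    return CylinderTarget()


@pytest.fixture(scope="session")
def prep_tc():
    """200 ng plasmid in 30 uL (the graded-activity protocol)."""
    return PlasmidPrep(mass_per_volume_ug_ml=0.2 / 0.030)


@pytest.fixture(scope="session")
def prep_i():
    """2 ug plasmid in 100 uL (the aliquot protocol)."""
    return PlasmidPrep(mass_per_volume_ug_ml=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
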
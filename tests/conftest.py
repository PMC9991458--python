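import numpy as np
import pytest

from tropofil import filament_model as fm
from tropofil import synthetic_md as smd


@pytest.fixture(scope="session")
def wt_params():
    return fm.ModelParameters.preset("wt")


@pytest.fixture(scope="session")
def mutant_params():
    return fm.ModelParameters.preset("s215l")


@pytest.fixture(scope="session")
def wt_baseline_delta():
    """Uniform flexibility level whose chain fits the WT stiffness exactly."""
    return smd.baseline_delta_for_stiffness(60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
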
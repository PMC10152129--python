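import numpy as np
import pytest
from hypothesis import settings

from lungpet.core import PAPER_FRAMING, make_frame_schedule
from lungpet.input_function import prepare_input
from lungpet.kinetics import KineticParams
from lungpet.synthetic import InputModel, simulate_subject, true_parent_plasma

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: canonical 2TC subject inside the study's parameter ranges
CANONICAL_2TC = KineticParams(K1=2.0, k2=4.0, k3=1.2, k4=1.0, vB=0.15)


@pytest.fixture(scope="session")
def input_model():
    return InputModel()


@pytest.fixture(scope="session")
def paper_schedule():
    return make_frame_schedule(PAPER_FRAMING)


@pytest.fixture(scope="session")
def canonical_params():
    return CANONICAL_2TC


@pytest.fixture(scope="session")
def canonical_subject(input_model):
    """Noiseless (lung, blood, blood-series) for the canonical 2TC subject."""
    return simulate_subject(CANONICAL_2TC, input_model, seed=0)


@pytest.fixture(scope="session")
def canonical_plasma(canonical_subject):
    """Metabolite-corrected plasma input reconstructed from framed data."""
    _, blood, bs = canonical_subject
    return prepare_input(blood, bs)


@pytest.fixture(scope="session")
def analytic_plasma(input_model):
    """The exact generating parent-plasma input (no reconstruction error)."""
    return true_parent_plasma(input_model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
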
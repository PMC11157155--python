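import numpy as np
import pytest

from znbox import rat_model, rat_observations
from znbox.model import BoxModel, Compartment, FluxSpec, delta_to_alpha


@pytest.fixture(scope="session")
def rat_fitted():
    return rat_model("fitted_final")


@pytest.fixture(scope="session")
def rat_obs():
    return rat_observations()


def make_single_box(mass=100.0, rate=20.0, d_in=0.0, d_out=0.0, diet=0.0):
    """diet -> box -> waste with optional fractionation on each leg."""
    return BoxModel(
        [
            Compartment("diet", role="source", delta0=diet),
            Compartment("box", mass=mass),
            Compartment("waste", role="sink"),
        ],
        [
            FluxSpec("diet", "box", rate, delta_to_alpha(d_in)),
            FluxSpec("box", "waste", rate, delta_to_alpha(d_out)),
        ],
    )


def make_two_box(m1=50.0, m2=2000.0, through=100.0, exchange=10.0):
    """Fast plasma-like box exchanging with a slow bone-like box."""
    return BoxModel(
        [
            Compartment("diet", role="source", delta0=0.0),
            Compartment("fast", mass=m1),
            Compartment("slow", mass=m2),
            Compartment("waste", role="sink"),
        ],
        [
            FluxSpec("diet", "fast", through),
            FluxSpec("fast", "slow", exchange),
            FluxSpec("slow", "fast", exchange),
            FluxSpec("fast", "waste", through),
        ],
    )


@pytest.fixture
def single_box():
    return make_single_box()


@pytest.fixture
def two_box():
    return make_two_box()


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
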
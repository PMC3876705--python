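import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from neopatch import netgen, workbench  # noqa: E402
from neopatch.dynamics import StimulusSpec  # noqa: E402
from neopatch.workbench import FixtureSpec  # noqa: E402


@pytest.fixture(scope="session")
def small_fixture():
    """256-neuron all-class network calibrated to 5000 expected edges, with
    its run config."""
    spec = FixtureSpec(name="unit", n_neurons=256, target_edges=5000, seed=1)
    return workbench.make_network_fixture(spec)


@pytest.fixture(scope="session")
def small_network(small_fixture):
    return small_fixture[0]


@pytest.fixture(scope="session")
def small_stimulus(small_fixture):
    network, cfg = small_fixture
    return workbench.build_stimulus(cfg, network)


@pytest.fixture(scope="session")
def line_network():
    """Ten superficial pyramidal cells on a line, no synapses."""
    neurons = pd.DataFrame({
        "id": np.arange(10),
        "cell_class": "SPYR",
        "x_um": np.arange(10) * 5.0,
        "y_um": np.zeros(10),
    })
    edges = pd.DataFrame(
        columns=["pre_id", "post_id", "delay_ms", "weight", "kind"])
    return netgen.Network(neurons=neurons, edges=edges)


@pytest.fixture(scope="session")
def pulse_stimulus():
    """Brief strong pulse to all ten line neurons (one evoked spike each)."""
    return StimulusSpec(target_ids=tuple(range(10)), amplitude_nA=1.5,
                        onset_ms=2.0, offset_ms=4.0)
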
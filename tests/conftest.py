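import numpy as np
import pytest

from mauthnet import AblationSpec, build_circuit
from mauthnet.choice_analysis import classify_outcomes
from mauthnet.circuit import CircuitVariant
from mauthnet.protocols import run_grid, stimulus_grid


@pytest.fixture(scope="session")
def default_circuit():
    """The full experimentally supported circuit at default parameters."""
    return build_circuit()


@pytest.fixture(scope="session")
def grid41(default_circuit):
    """The default 41 x 41 stimulus grid."""
    return stimulus_grid(default_circuit, n=41)


@pytest.fixture(scope="session")
def variant_maps(grid41):
    """Choice maps of all seven circuit variants on the default grid."""
    maps = {}
    for v in CircuitVariant:
        circ = build_circuit(v)
        maps[v.value] = classify_outcomes(run_grid(circ, grid41))
    return maps


@pytest.fixture(scope="session")
def ablated_right_map(grid41):
    """Choice map after removing the entire right FF pool."""
    circ = build_circuit(
        ablations=[AblationSpec("FF_pool", "right", "all")])
    return classify_outcomes(run_grid(circ, grid41))


@pytest.fixture(scope="session")
def small_map(default_circuit):
    """A coarse (9 x 9) choice map of the full circuit, for cheap checks."""
    grid = stimulus_grid(default_circuit, n=9)
    return classify_outcomes(run_grid(default_circuit, grid))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
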
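import numpy as np
import pytest

from tmedyn import build_hnscc_network, nominal_parameters
from tmedyn.sweep import default_design, run_sweep

# toy-network builders used across test modules
from tmedyn.core import CELL_STATE, EdgeSpec, NetworkSpec, NodeSpec, ParameterSet


@pytest.fixture(scope="session")
def network():
    return build_hnscc_network()


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def landscape_sweep():
    """The seeded 1000-sample steady-state landscape (shared: it is the
    expensive fixture behind the five-group and classifier-stability checks).
    """
    return run_sweep(default_design(1000, seed=7), keep_records=False)


def logistic_toy(kprol=1.0, xmax=1.0, kd=0.0):
    """One self-limiting cell state; closed-form logistic dynamics."""
    nodes = [NodeSpec("A", CELL_STATE)]
    edges = [
        EdgeSpec("proliferation", "A", parameter_keys=("Kprol", "xmax")),
        EdgeSpec("death", "A", parameter_keys=("KD",)),
    ]
    params = ParameterSet({"Kprol": kprol, "xmax": xmax, "KD": kd})
    return NetworkSpec(nodes, edges, name="logistic_toy"), params


def conversion_toy(kconv=1.0):
    """Two cell states coupled by a pure conversion (mass conserving)."""
    nodes = [NodeSpec("A", CELL_STATE), NodeSpec("B", CELL_STATE)]
    edges = [EdgeSpec("conversion", "B", "A", parameter_keys=("Kconv",))]
    params = ParameterSet({"Kconv": kconv})
    return NetworkSpec(nodes, edges, name="conversion_toy"), params
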
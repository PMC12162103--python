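"""Random-but-valid parameter sets and initial conditions for testing.

The generator jitters the nominal registry multiplicatively (log-normal,
default sigma of 0.3 decades) and draws initial states uniformly below the
relevant carrying capacities — the kind of variation a parameter-uncertain
but structurally intact TME model should tolerate without solver failure.
"""

from __future__ import annotations

import numpy as np

from .core import NetworkSpec, ParameterSet
from .hnscc import MOLECULAR_NODES, build_hnscc_network, nominal_parameters

__all__ = ["random_parameters", "random_state", "random_model"]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_parameters(
    seed_or_rng,
    *,
    sigma_decades: float = 0.3,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """A valid registry jittered around the nominal values.

    Proximity/accessibility fractions (``alpha*`` keys) are capped at 1;
    exact zeros (e.g. an unused drug dose) stay zero.
    """
    rng = _rng(seed_or_rng)
    base = base or nominal_parameters()
    values = {}
    for key, value in base.items():
        if value == 0.0:
            values[key] = 0.0
            continue
        jittered = value * 10.0 ** rng.normal(0.0, sigma_decades)
        if key.startswith("alpha"):
            jittered = min(jittered, 1.0)
        values[key] = jittered
    return ParameterSet(values)


def random_state(
    seed_or_rng,
    network: NetworkSpec | None = None,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """A nonnegative state: cells uniform below capacity, species in [0, 20]."""
    rng = _rng(seed_or_rng)
    network = network or build_hnscc_network()
    params = params or nominal_parameters()
    caps = {
        "C0": "xmax_tumor", "Cn": "xmax_tumor", "Cp": "xmax_tumor",
        "TKp": "xmax_TK", "TKn": "xmax_TK", "TEx": "xmax_TK",
        "THelp": "xmax_THelp", "TReg": "xmax_TReg",
        "M1": "xmax_M", "M2": "xmax_M", "FWT": "xmax_fib", "CAF": "xmax_fib",
    }
    x = np.empty(network.n_nodes)
    for i, node in enumerate(network.nodes):
        if node.name in MOLECULAR_NODES:
            x[i] = rng.uniform(0.0, 20.0)
        else:
            cap_key = caps.get(node.family or node.name, "xmax_tumor")
            x[i] = rng.uniform(0.0, params[cap_key])
    return x


def random_model(seed: int) -> tuple[NetworkSpec, ParameterSet, np.ndarray]:
    """Convenience bundle: the HNSCC network with jittered parameters and a
    random nonnegative initial state, all driven by one seed."""
    rng = _rng(seed)
    network = build_hnscc_network()
    params = random_parameters(rng)
    return network, params, random_state(rng, network, params)
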
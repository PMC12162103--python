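"""Model and state transformations for in-silico treatment experiments.

Three intervention families:

* **anti-PD1** (immune checkpoint inhibition): removes the PD1 program from
  killer T cells.  Modeled as a drug-driven conversion ``TKp -> TKn`` at rate
  ``k_bind * dose`` plus enabling ``TKn`` to eliminate exposed PDL1+ tumor
  cells (PD1- killers recognize them as antigen-presenting).  ``TKn`` carries
  no PD1 program, so it is immune to the exhaustion conversion.
* **one-time IL-2 spike**: an additive bump of the IL-2 initial condition.
* **species knockout / reduction**: either scale all secretion of a species
  by ``1 - fraction`` (``production_zero``, the default, used for graded
  "reduction rates") or attach a fast absorbing sink (``clamp_zero``,
  intended for idealized full knockouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MOLECULAR_SPECIES,
    EdgeSpec,
    InvalidParameterError,
    NetworkSpec,
    ParameterSet,
)

__all__ = [
    "InterventionSpec",
    "apply_anti_pd1",
    "il2_spike",
    "knockout",
]

_KINDS = frozenset({"anti_pd1", "il2_spike", "knockout", "reduction"})

# clamp-mode sink: extra first-order removal, fast against any biological rate
_CLAMP_SINK = 1.0e4


@dataclass(frozen=True)
class InterventionSpec:
    """Declarative description of one intervention.

    ``magnitude`` is the anti-PD1 dose, the IL-2 spike amplitude, or the
    knocked-out fraction; ``timing`` the application time in days.
    """

    kind: str
    target: str
    magnitude: float
    timing: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.magnitude < 0:
            raise InvalidParameterError("magnitude must be nonnegative")


def apply_anti_pd1(
    network: NetworkSpec,
    params: ParameterSet,
    dose: float,
    k_bind: float | None = None,
    *,
    block_exhaustion_fraction: float = 0.0,
) -> tuple[NetworkSpec, ParameterSet]:
    """Return the treated (network, params) pair.

    At ``dose = 0`` the model is returned unchanged (identity).  Otherwise a
    ``TKp -> TKn`` conversion edge at rate ``k_bind * dose`` is added and
    ``TKn`` gains an elimination edge against exposed PDL1+ tumor cells,
    scaled by accessibility like every other elimination (its barrier-
    penetration leak into the protected pool is attached automatically).

    ``block_exhaustion_fraction`` optionally also scales the residual
    exhaustion rate of the remaining PD1+ killers by ``1 - fraction`` (off by
    default: the drug converts, it does not shield).
    """
    if dose < 0:
        raise InvalidParameterError(f"dose must be nonnegative, got {dose}")
    if k_bind is None:
        k_bind = params["k_bind_pd1"]
    if k_bind < 0:
        raise InvalidParameterError(f"k_bind must be nonnegative, got {k_bind}")
    if not 0.0 <= block_exhaustion_fraction <= 1.0:
        raise InvalidParameterError("block_exhaustion_fraction must be in [0,1]")
    if dose == 0:
        return network, params

    changes: dict[str, float] = {"dose_pd1": dose, "k_bind_pd1": k_bind}
    extra = [
        EdgeSpec(
            "conversion", "TKn", "TKp",
            parameter_keys=("k_bind_pd1", "dose_pd1"),
        ),
        EdgeSpec(
            "elimination", "Cp_E", "TKn",
            parameter_keys=("Kkill", "alpha_ac"),
        ),
    ]
    if block_exhaustion_fraction > 0:
        changes["Kconv_exh"] = params["Kconv_exh"] * (1.0 - block_exhaustion_fraction)
    return network.with_edges(extra), params.updated(changes)


def il2_spike(
    x0: np.ndarray,
    amplitude: float,
    network: NetworkSpec | None = None,
) -> np.ndarray:
    """Return ``x0`` with the IL-2 entry incremented by ``amplitude``."""
    if amplitude < 0:
        raise InvalidParameterError(f"amplitude must be nonnegative, got {amplitude}")
    if network is None:
        from .hnscc import build_hnscc_network

        network = build_hnscc_network()
    out = np.array(x0, dtype=float, copy=True)
    out[network.index("IL2")] += amplitude
    return out


def knockout(
    network: NetworkSpec,
    params: ParameterSet,
    species: str,
    mode: str = "production_zero",
    fraction: float = 1.0,
) -> tuple[NetworkSpec, ParameterSet]:
    """Knock out (or partially reduce) a molecular species.

    ``production_zero`` multiplies every secretion flux of the species by
    ``1 - fraction``; ``clamp_zero`` attaches a fast absorbing sink scaled by
    ``fraction`` (exact suppression only at ``fraction = 1``).  ``fraction = 0``
    is the identity in both modes.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidParameterError(f"fraction must be in [0,1], got {fraction}")
    node = network.node(species)
    if node.role != MOLECULAR_SPECIES:
        raise InvalidParameterError(
            f"knockout target must be a molecular species, got cell state {species!r}"
        )
    if mode not in ("production_zero", "clamp_zero"):
        raise ValueError(f"unknown knockout mode {mode!r}")
    if fraction == 0.0:
        return network, params

    if mode == "production_zero":
        key = f"_ko_{species}"
        edges = []
        for edge in network.edges:
            if edge.kind == "secretion" and species in network.members(edge.target):
                edge = EdgeSpec(
                    "secretion", edge.target, edge.source,
                    parameter_keys=edge.parameter_keys + (key,),
                )
            edges.append(edge)
        return (
            NetworkSpec(list(network.nodes), edges, groups=network.groups,
                        name=network.name),
            params.updated({key: 1.0 - fraction}),
        )

    # clamp_zero: multiply the species' degradation rate by a fast sink
    key = f"_clamp_{species}"
    edges = []
    for edge in network.edges:
        if edge.kind == "degradation" and species in network.members(edge.target):
            edge = EdgeSpec(
                "degradation", edge.target,
                parameter_keys=edge.parameter_keys + (key,),
            )
        edges.append(edge)
    sink = 1.0 + _CLAMP_SINK * fraction
    return (
        NetworkSpec(list(network.nodes), edges, groups=network.groups,
                    name=network.name),
        params.updated({key: sink}),
    )
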
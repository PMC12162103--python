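"""Flux-rule algebra and right-hand-side assembly for cell-state TME models.

The model is a deterministic, spatially homogeneous ODE system over two kinds
of nodes: *cell states* (populations) and *molecular species* (concentrations).
Dynamics are assembled from a small set of typed flux rules:

* ``proliferation`` — logistic growth ``Kprol * x * (1 - x/xmax)``;
* ``conversion`` — first-order transfer between cell states, optionally gated
  by saturating occupancy factors ``m/(V+m)`` of promoter species;
* ``paracrine`` — a bounded multiplier ``1 + Kpara*alpha*s/(V + a*s)`` applied
  to the target's proliferation flux;
* ``regulatory_inhibition`` — a factor ``1/(Vreg + alpha*s)`` applied to a
  target's proliferation, secretion, or elimination flux;
* ``elimination`` — mass-action killing ``Kkill * alpha_ac * x_target * x_killer``,
  removed from the target only;
* ``death`` / ``degradation`` — first-order decay ``KD * x``;
* ``secretion`` — first-order production of a species by a cell state.

Tumor cell states may exist in *exposed* and *protected* compartment copies
(immune-accessible vs CAF-shielded); the assembler couples the copies through
a shared, accessibility-partitioned carrying capacity, first-order exchange,
and a barrier-penetration leak of elimination into the protected pool.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "NetworkSpec",
    "ParameterSet",
    "AssemblyError",
    "InvalidParameterError",
    "flux_proliferation",
    "flux_conversion",
    "paracrine_multiplier",
    "regulatory_factor",
    "flux_elimination",
    "flux_death",
    "assemble_rhs",
    "count_states_params",
]

CELL_STATE = "cell_state"
MOLECULAR_SPECIES = "molecular_species"
_ROLES = frozenset({CELL_STATE, MOLECULAR_SPECIES})
_COMPARTMENTS = frozenset({"exposed", "protected", "global"})

EDGE_KINDS = frozenset(
    {
        "proliferation",
        "conversion",
        "paracrine",
        "regulatory_inhibition",
        "elimination",
        "death",
        "secretion",
        "degradation",
    }
)
_SOURCE_REQUIRED = frozenset(
    {"conversion", "paracrine", "regulatory_inhibition", "elimination", "secretion"}
)
_SOURCE_FREE = frozenset({"proliferation", "death", "degradation"})


class InvalidParameterError(ValueError):
    """A flux primitive was called with an out-of-domain argument."""


class AssemblyError(ValueError):
    """The network/parameter pair cannot be compiled into an ODE system."""


# ---------------------------------------------------------------------------
# flux primitives (rules 2-7)
# ---------------------------------------------------------------------------


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise InvalidParameterError(f"{name} must be nonnegative, got {value}")


def flux_proliferation(Kprol: float, x: float, xmax: float) -> float:
    """Logistic proliferation flux ``Kprol * x * (1 - x/xmax)``.

    Zero at ``x = 0`` and at carrying capacity; negative above capacity
    (relaxation back toward ``xmax``).
    """
    if xmax <= 0:
        raise InvalidParameterError(f"carrying capacity must be positive, got {xmax}")
    _check_nonneg(Kprol=Kprol, x=x)
    return Kprol * x * (1.0 - x / xmax)


def flux_conversion(Kconv: float, x_source: float) -> float:
    """First-order conversion flux ``Kconv * x_source``.

    The same flux is subtracted from the source state and added to the target
    state, so a conversion edge conserves cell number at the flux level.
    """
    _check_nonneg(Kconv=Kconv, x_source=x_source)
    return Kconv * x_source


def paracrine_multiplier(
    Kpara: float, alpha: float, V: float, a: float, xi: float
) -> float:
    """Bounded proliferation multiplier ``1 + Kpara*alpha*xi/(V + a*xi)``.

    ``alpha`` is the spatial proximity index in [0, 1]; the multiplier lies in
    ``[1, 1 + Kpara*alpha/a)`` and is monotone nondecreasing in ``xi``.
    """
    if V <= 0:
        raise InvalidParameterError(f"dissociation constant V must be positive, got {V}")
    if a <= 0:
        raise InvalidParameterError(f"saturation coefficient a must be positive, got {a}")
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(f"proximity index alpha must be in [0,1], got {alpha}")
    _check_nonneg(Kpara=Kpara, xi=xi)
    return 1.0 + Kpara * alpha * xi / (V + a * xi)


def regulatory_factor(Vreg: float, alpha: float, xi: float) -> float:
    """Regulatory-inhibition factor ``1/(Vreg + alpha*xi)``.

    Multiplies the target's proliferation (or secretion/elimination) flux;
    strictly decreasing in the inhibitor level ``xi``.
    """
    if Vreg <= 0:
        raise InvalidParameterError(f"Vreg must be positive, got {Vreg}")
    _check_nonneg(alpha=alpha, xi=xi)
    return 1.0 / (Vreg + alpha * xi)


def flux_elimination(
    Kkill: float, alpha_ac: float, x_target: float, x_killer: float
) -> float:
    """Mass-action elimination flux ``Kkill * alpha_ac * x_target * x_killer``.

    Subtracted from the target population only (the killer is not consumed).
    """
    _check_nonneg(Kkill=Kkill, x_target=x_target, x_killer=x_killer)
    if not 0.0 <= alpha_ac <= 1.0:
        raise InvalidParameterError(f"alpha_ac must be in [0,1], got {alpha_ac}")
    return Kkill * alpha_ac * x_target * x_killer


def flux_death(KD: float, x: float) -> float:
    """Natural death (cells) or degradation (species) flux ``KD * x``."""
    _check_nonneg(KD=KD, x=x)
    return KD * x


# ---------------------------------------------------------------------------
# network description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """One state variable of the model.

    ``family`` links exposed/protected compartment copies of the same tumor
    cell state (e.g. ``C0_E`` and ``C0_P`` both carry ``family='C0'``); it is
    also usable as a pooled edge endpoint meaning "sum of the copies".
    """

    name: str
    role: str
    compartment: str = "global"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown node role {self.role!r}")
        if self.compartment not in _COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.compartment != "global":
            if self.role != CELL_STATE:
                raise ValueError(
                    f"node {self.name!r}: only cell states may be compartmentalized"
                )
            if self.family is None:
                raise ValueError(
                    f"node {self.name!r}: compartmentalized nodes need a family"
                )


@dataclass(frozen=True)
class EdgeSpec:
    """One typed flux rule.

    ``source``/``target`` may name a node, a family, or a declared group (the
    pooled population is used).  ``modulators`` are ``(species, V_key)`` pairs
    attaching saturating occupancy gates ``m/(V+m)`` to a conversion flux.
    ``applies_to`` selects which flux a regulatory_inhibition edge scales.
    """

    kind: str
    target: str
    source: str | None = None
    parameter_keys: tuple[str, ...] = ()
    modulators: tuple[tuple[str, str], ...] = ()
    applies_to: str = "proliferation"

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.kind in _SOURCE_REQUIRED and self.source is None:
            raise ValueError(f"{self.kind} edge to {self.target!r} requires a source")
        if self.kind in _SOURCE_FREE and self.source is not None:
            raise ValueError(f"{self.kind} edge to {self.target!r} takes no source")
        if self.applies_to not in ("proliferation", "secretion", "elimination"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")
        if self.modulators and self.kind != "conversion":
            raise ValueError("modulators are only valid on conversion edges")


class NetworkSpec:
    """An immutable atlas of nodes, typed flux edges, and pooled groups."""

    def __init__(
        self,
        nodes: list[NodeSpec],
        edges: list[EdgeSpec],
        groups: dict[str, tuple[str, ...]] | None = None,
        name: str = "",
    ) -> None:
        names = [node.name for node in nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique within a NetworkSpec")
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.edges: tuple[EdgeSpec, ...] = tuple(edges)
        self.name = name
        self._index = {node.name: i for i, node in enumerate(self.nodes)}

        groups = dict(groups or {})
        # every family is implicitly a pooled group
        for node in self.nodes:
            if node.family is not None:
                groups.setdefault(node.family, ())
        families: dict[str, list[str]] = {}
        for node in self.nodes:
            if node.family is not None:
                families.setdefault(node.family, []).append(node.name)
        for fam, members in families.items():
            if not groups.get(fam):
                groups[fam] = tuple(members)
        self.groups: dict[str, tuple[str, ...]] = {
            g: tuple(members) for g, members in groups.items()
        }
        for group, members in self.groups.items():
            if group in self._index:
                raise ValueError(f"group {group!r} collides with a node name")
            for member in members:
                if member not in self._index:
                    raise ValueError(f"group {group!r} refers to unknown node {member!r}")
        for edge in self.edges:
            for endpoint in (edge.source, edge.target):
                if endpoint is not None and not self._known(endpoint):
                    raise ValueError(
                        f"{edge.kind} edge ({edge.source!r} -> {edge.target!r}) "
                        f"references unknown node/group {endpoint!r}"
                    )
            for species, _ in edge.modulators:
                if not self._known(species):
                    raise ValueError(f"unknown modulator species {species!r}")

    # -- queries ----------------------------------------------------------

    def _known(self, name: str) -> bool:
        return name in self._index or name in self.groups

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(node.name for node in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self._index[name]]

    def members(self, name: str) -> tuple[str, ...]:
        """Resolve a node/family/group name to its member node names."""
        if name in self._index:
            return (name,)
        return self.groups[name]

    def cell_states(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.role == CELL_STATE)

    def molecular_species(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.role == MOLECULAR_SPECIES)

    def edges_of(self, kind: str) -> tuple[EdgeSpec, ...]:
        return tuple(e for e in self.edges if e.kind == kind)

    def edges_into(self, node: str, kind: str | None = None) -> tuple[EdgeSpec, ...]:
        out = []
        for e in self.edges:
            if kind is not None and e.kind != kind:
                continue
            if node in self.members(e.target):
                out.append(e)
        return tuple(out)

    def edges_from(self, node: str, kind: str | None = None) -> tuple[EdgeSpec, ...]:
        out = []
        for e in self.edges:
            if e.source is None:
                continue
            if kind is not None and e.kind != kind:
                continue
            if node in self.members(e.source):
                out.append(e)
        return tuple(out)

    def without_node(self, name: str) -> "NetworkSpec":
        """A copy with a node removed, along with every edge touching it."""
        if name not in self._index:
            raise KeyError(name)
        nodes = [n for n in self.nodes if n.name != name]
        keep = []
        for e in self.edges:
            touched = set(self.members(e.target))
            if e.source is not None:
                touched |= set(self.members(e.source))
            touched |= {s for s, _ in e.modulators}
            if name not in touched:
                keep.append(e)
        groups = {
            g: tuple(m for m in members if m != name)
            for g, members in self.groups.items()
        }
        groups = {g: m for g, m in groups.items() if m}
        return NetworkSpec(nodes, keep, groups=groups, name=self.name)

    def with_edges(self, extra: list[EdgeSpec]) -> "NetworkSpec":
        return NetworkSpec(
            list(self.nodes), list(self.edges) + list(extra),
            groups=self.groups, name=self.name,
        )

    def parameter_keys(self) -> set[str]:
        keys: set[str] = set()
        for e in self.edges:
            keys.update(e.parameter_keys)
            keys.update(v for _, v in e.modulators)
        return keys

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"NetworkSpec({self.name or 'unnamed'}: "
            f"{self.n_nodes} nodes, {len(self.edges)} edges)"
        )


class ParameterSet(Mapping):
    """Named registry of rate constants, capacities, and hyperparameters.

    All values must be finite and nonnegative; carrying capacities (keys
    prefixed ``xmax``) must be strictly positive.
    """

    def __init__(self, values: Mapping[str, float]) -> None:
        checked: dict[str, float] = {}
        for key, value in values.items():
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(
                    f"parameter {key!r} must be finite and nonnegative, got {value}"
                )
            if key.startswith("xmax") and value <= 0:
                raise InvalidParameterError(
                    f"carrying capacity {key!r} must be positive, got {value}"
                )
            checked[key] = value
        self._values = checked

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def updated(self, changes: Mapping[str, float]) -> "ParameterSet":
        """A copy with ``changes`` applied (new keys allowed)."""
        merged = dict(self._values)
        merged.update(changes)
        return ParameterSet(merged)

    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        """A copy with selected entries multiplied by given factors."""
        merged = dict(self._values)
        for key, factor in factors.items():
            merged[key] = merged[key] * factor
        return ParameterSet(merged)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({len(self._values)} entries)"


# ---------------------------------------------------------------------------
# RHS assembly
# ---------------------------------------------------------------------------

# accessibility/compartment machinery keys (present only in compartment models)
ALPHA_ACC = "alpha_acc"
KBR = "Kbr"
DELTA = "delta"
KMIG = "Kmig"


@dataclass
class _Prolif:
    node: int
    kprol: float
    cap: float
    pool: int  # 0 = own capacity, 1 = exposed pool, 2 = protected pool
    factors: list = field(default_factory=list)  # (kind, args...) multipliers


class CompiledRHS:
    """Callable ``f(t, x) -> dx/dt`` compiled from a NetworkSpec + ParameterSet.

    Parameter values are bound at assembly time; the per-call work is pure
    arithmetic over precomputed index lists, which keeps stiff integration of
    a ~24-state system fast enough for thousand-sample parameter sweeps.
    """

    def __init__(
        self,
        network: NetworkSpec,
        params: ParameterSet,
        frozen_ia: float | None = None,
    ) -> None:
        self.network = network
        self.params = params
        self.frozen_ia = frozen_ia
        self.n = network.n_nodes
        self._build()

    # -- assembly ---------------------------------------------------------

    def _resolve_param(self, edge: EdgeSpec, key: str) -> float:
        try:
            return self.params[key]
        except KeyError:
            raise AssemblyError(
                f"{edge.kind} edge ({edge.source!r} -> {edge.target!r}): "
                f"unresolved parameter {key!r}"
            ) from None

    def _idx(self, name: str) -> list[int]:
        return [self.network.index(m) for m in self.network.members(name)]

    def _single(self, edge: EdgeSpec, name: str) -> int:
        members = self.network.members(name)
        if len(members) != 1:
            raise AssemblyError(
                f"{edge.kind} edge ({edge.source!r} -> {edge.target!r}): "
                f"endpoint {name!r} must be a single node"
            )
        return self.network.index(members[0])

    def _build(self) -> None:
        net, params = self.network, self.params

        # accessibility machinery is active iff compartment copies exist and
        # the registry carries the barrier hyperparameters
        exposed = [i for i, nd in enumerate(net.nodes) if nd.compartment == "exposed"]
        protected = [i for i, nd in enumerate(net.nodes) if nd.compartment == "protected"]
        self.exposed_idx = exposed
        self.protected_idx = protected
        self.has_access = bool(exposed) and all(
            k in params for k in (ALPHA_ACC, KBR, DELTA)
        )
        if self.has_access:
            if "CAF" not in net.node_names:
                raise AssemblyError("accessibility machinery requires a CAF node")
            self.i_caf = net.index("CAF")
            self.ia_mul = params[ALPHA_ACC] * params[KBR]
            self.pen_mul = params[ALPHA_ACC] ** 2 * params[DELTA]
        else:
            self.i_caf = -1
            self.ia_mul = 0.0
            self.pen_mul = 0.0

        # protected partner of each exposed node, by family
        partner: dict[int, int] = {}
        by_family: dict[str, dict[str, int]] = {}
        for i, nd in enumerate(net.nodes):
            if nd.compartment != "global":
                by_family.setdefault(nd.family, {})[nd.compartment] = i
        for fam, comp in by_family.items():
            if set(comp) == {"exposed", "protected"}:
                partner[comp["exposed"]] = comp["protected"]
        self._partner = partner

        self.kmig = params[KMIG] if (KMIG in params and partner) else 0.0

        # proliferation terms
        prolif: dict[int, _Prolif] = {}
        pool_cap_key: str | None = None
        for edge in net.edges_of("proliferation"):
            j = self._single(edge, edge.target)
            if j in prolif:
                raise AssemblyError(
                    f"node {net.nodes[j].name!r}: proliferation flux defined twice"
                )
            kprol_key, xmax_key = edge.parameter_keys
            kprol = self._resolve_param(edge, kprol_key)
            cap = self._resolve_param(edge, xmax_key)
            nd = net.nodes[j]
            if nd.compartment == "exposed" and self.has_access:
                pool = 1
            elif nd.compartment == "protected" and self.has_access:
                pool = 2
            else:
                pool = 0
            if pool:
                if pool_cap_key is not None and pool_cap_key != xmax_key:
                    raise AssemblyError(
                        "compartmentalized tumor states must share one capacity"
                    )
                pool_cap_key = xmax_key
            prolif[j] = _Prolif(j, kprol, cap, pool)
        self.pool_cap = params[pool_cap_key] if pool_cap_key else 0.0

        # paracrine multipliers and regulatory factors on proliferation
        for edge in net.edges_of("paracrine"):
            kpara_key, v_key, alpha_key = edge.parameter_keys
            kpara = self._resolve_param(edge, kpara_key)
            v = self._resolve_param(edge, v_key)
            alpha = self._resolve_param(edge, alpha_key)
            if v <= 0:
                raise AssemblyError(f"paracrine edge {edge}: V must be positive")
            src = self._idx(edge.source)
            for j in self._idx(edge.target):
                if j not in prolif:
                    raise AssemblyError(
                        f"paracrine edge into {net.nodes[j].name!r}: "
                        "target has no proliferation flux"
                    )
                prolif[j].factors.append(("para", kpara, v, alpha, src))

        reg_elim: dict[int, list[tuple[float, float, list[int]]]] = {}
        reg_secr: dict[int, list[tuple[float, float, list[int]]]] = {}
        for edge in net.edges_of("regulatory_inhibition"):
            v_key, alpha_key = edge.parameter_keys
            v = self._resolve_param(edge, v_key)
            alpha = self._resolve_param(edge, alpha_key)
            if v <= 0:
                raise AssemblyError(f"regulatory edge {edge}: Vreg must be positive")
            src = self._idx(edge.source)
            for j in self._idx(edge.target):
                if edge.applies_to == "proliferation":
                    if j not in prolif:
                        raise AssemblyError(
                            f"regulatory edge into {net.nodes[j].name!r}: "
                            "target has no proliferation flux"
                        )
                    prolif[j].factors.append(("reg", v, alpha, src))
                elif edge.applies_to == "elimination":
                    reg_elim.setdefault(j, []).append((v, alpha, src))
                else:
                    reg_secr.setdefault(j, []).append((v, alpha, src))

        self.prolif_terms = [
            (p.node, p.kprol, p.cap, p.pool, p.factors) for p in prolif.values()
        ]

        # conversions; the rate is the product of all parameter keys, so a
        # drug-induced conversion can carry (binding rate, dose) as a pair
        conversions = []
        for edge in net.edges_of("conversion"):
            jsrc = self._single(edge, edge.source)
            jtgt = self._single(edge, edge.target)
            k = math.prod(self._resolve_param(edge, key) for key in edge.parameter_keys)
            gates = []
            for species, v_key in edge.modulators:
                gates.append((self._idx(species), self._resolve_param(edge, v_key)))
            conversions.append((jsrc, jtgt, k, gates))
        self.conversions = conversions

        # eliminations; protected-compartment leak attached automatically
        eliminations = []
        for edge in net.edges_of("elimination"):
            jkill = self._single(edge, edge.source)
            jtgt = self._single(edge, edge.target)
            if net.nodes[jtgt].compartment == "protected":
                raise AssemblyError(
                    f"elimination edge targets protected node {net.nodes[jtgt].name!r}"
                )
            rate = math.prod(
                self._resolve_param(edge, key) for key in edge.parameter_keys
            )
            regs = reg_elim.get(jkill, [])
            leak = partner.get(jtgt, -1)
            eliminations.append((jkill, jtgt, rate, regs, leak))
        self.eliminations = eliminations

        # death & degradation (first-order decay)
        decay_seen: set[int] = set()
        decays = []
        for kind in ("death", "degradation"):
            for edge in net.edges_of(kind):
                j = self._single(edge, edge.target)
                if j in decay_seen:
                    raise AssemblyError(
                        f"node {net.nodes[j].name!r}: {kind} flux defined twice"
                    )
                decay_seen.add(j)
                expected = CELL_STATE if kind == "death" else MOLECULAR_SPECIES
                if net.nodes[j].role != expected:
                    raise AssemblyError(
                        f"{kind} edge on {net.nodes[j].name!r} has wrong node role"
                    )
                rate = math.prod(
                    self._resolve_param(edge, key) for key in edge.parameter_keys
                )
                decays.append((j, rate))
        self.decays = decays

        # secretions
        secretions = []
        for edge in net.edges_of("secretion"):
            j = self._single(edge, edge.target)
            if net.nodes[j].role != MOLECULAR_SPECIES:
                raise AssemblyError(
                    f"secretion edge must target a molecular species, "
                    f"got {net.nodes[j].name!r}"
                )
            src = self._idx(edge.source)
            ksec = math.prod(
                self._resolve_param(edge, key) for key in edge.parameter_keys
            )
            secretions.append((j, ksec, src, reg_secr.get(j, [])))
        self.secretions = secretions

    # -- evaluation -------------------------------------------------------

    def accessibility(self, x: np.ndarray) -> float:
        """Instantaneous immune accessibility index for a state vector."""
        if not self.has_access:
            return 1.0
        if self.frozen_ia is not None:
            return self.frozen_ia
        return 1.0 - math.tanh(self.ia_mul * x[self.i_caf])

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        # fluxes are evaluated on the nonnegative part of the state: a tiny
        # negative solver overshoot must not feed back through the logistic
        # terms (for x < 0 they are destabilizing); a weak restoring term
        # below pulls such excursions back to zero
        xneg = np.minimum(x, 0.0)
        x = np.maximum(x, 0.0)
        dx = np.zeros(self.n)
        ia = 1.0
        pen = 1.0
        if self.has_access:
            caf = x[self.i_caf]
            ia = (
                self.frozen_ia
                if self.frozen_ia is not None
                else 1.0 - math.tanh(self.ia_mul * caf)
            )
            pen = math.exp(-self.pen_mul * caf * caf)

        occ_e = occ_p = 0.0
        if self.exposed_idx and self.pool_cap:
            # floor Ia away from exact zero (tanh saturates in floats) and cap
            # the crowding term: a pool whose capacity collapsed decays at a
            # bounded (but fast) per-capita rate instead of a stiff spike
            ia_eff = max(ia, 1e-9)
            k_ia = self.pool_cap * ia_eff / (1.0 + ia_eff)
            k_fp = self.pool_cap / (1.0 + ia_eff)
            tot_e = sum(x[i] for i in self.exposed_idx)
            tot_p = sum(x[i] for i in self.protected_idx)
            occ_e = min(tot_e / k_ia, 101.0)
            occ_p = min(tot_p / k_fp, 101.0)

        for j, kprol, cap, pool, factors in self.prolif_terms:
            if pool == 1:
                flux = kprol * x[j] * (1.0 - occ_e)
            elif pool == 2:
                flux = kprol * x[j] * (1.0 - occ_p)
            else:
                flux = kprol * x[j] * (1.0 - x[j] / cap)
            for f in factors:
                if f[0] == "para":
                    _, kpara, v, alpha, src = f
                    s = sum(x[i] for i in src)
                    flux *= 1.0 + kpara * alpha * s / (v + s)
                else:
                    _, v, alpha, src = f
                    s = sum(x[i] for i in src)
                    flux *= 1.0 / (v + alpha * s)
            dx[j] += flux

        for jsrc, jtgt, k, gates in self.conversions:
            flux = k * x[jsrc]
            for src, v in gates:
                s = sum(x[i] for i in src)
                flux *= s / (v + s)
            dx[jsrc] -= flux
            dx[jtgt] += flux

        for jkill, jtgt, kbase, regs, leak in self.eliminations:
            rate = kbase * x[jkill]
            for v, alpha, src in regs:
                s = sum(x[i] for i in src)
                rate *= 1.0 / (v + alpha * s)
            dx[jtgt] -= rate * x[jtgt]
            if leak >= 0:
                dx[leak] -= rate * pen * x[leak]

        for j, kd in self.decays:
            dx[j] -= kd * x[j]

        for j, ksec, src, regs in self.secretions:
            flux = ksec * sum(x[i] for i in src)
            for v, alpha, rsrc in regs:
                s = sum(x[i] for i in rsrc)
                flux *= 1.0 / (v + alpha * s)
            dx[j] += flux

        if self.kmig:
            for je, jp in self._partner.items():
                out = self.kmig * (1.0 - ia) * x[je]
                back = self.kmig * ia * x[jp]
                dx[je] += back - out
                dx[jp] += out - back

        dx -= xneg  # restore negative excursions at unit rate
        return dx

    def conversion_fluxes(self, x: np.ndarray) -> dict[tuple[str, str], float]:
        """Instantaneous conversion fluxes keyed by (source, target) names."""
        names = self.network.node_names
        out = {}
        for jsrc, jtgt, k, gates in self.conversions:
            flux = k * x[jsrc]
            for src, v in gates:
                s = sum(x[i] for i in src)
                flux *= s / (v + s)
            out[(names[jsrc], names[jtgt])] = flux
        return out


def assemble_rhs(
    network: NetworkSpec,
    params: ParameterSet,
    frozen_ia: float | None = None,
) -> CompiledRHS:
    """Compile a network + parameter registry into ``f(t, x) -> dx/dt``.

    ``frozen_ia`` pins the immune accessibility index to a constant instead of
    recomputing it from the instantaneous CAF population (used for scans over
    accessibility regimes).
    """
    return CompiledRHS(network, params, frozen_ia=frozen_ia)


def count_states_params(network: NetworkSpec, params: ParameterSet) -> tuple[int, int]:
    """Number of state variables and registry entries consumed by the model.

    Counts the registry keys referenced by the network's edges, plus the
    accessibility/compartment machinery keys when compartment copies exist,
    plus declared intervention parameters.  The full HNSCC atlas with its
    nominal registry consumes all 91 entries; removing the protected tumor
    compartments deactivates the barrier machinery and shrinks the count.
    """
    keys = network.parameter_keys() & set(params)
    if any(n.compartment != "global" for n in network.nodes):
        keys |= {k for k in (ALPHA_ACC, KBR, DELTA, KMIG) if k in params}
    keys |= {k for k in ("k_bind_pd1", "dose_pd1") if k in params}
    return network.n_nodes, len(keys)
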
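"""The HNSCC tumor-microenvironment instantiation of the flux-rule model.

24 state variables: 15 cell states (three tumor states, each split into a
killer-T-*exposed* and a CAF-*protected* compartment copy; five T-cell states;
two macrophage phases; wild-type fibroblasts and CAF) plus nine molecular
species (IL-2, IL-8, IL-10, LIF, IFNg, IRF8, OPN, ICAM1, lactate).

Node name conventions::

    C0_E / C0_P      stem-like tumor cells (exposed / protected)
    Cn_E / Cn_P      PDL1- tumor cells
    Cp_E / Cp_P      PDL1+ tumor cells
    TKp / TKn        PD1+ / PD1- killer T cells
    THelp, TReg, TEx helper, regulatory, exhausted T cells
    M1, M2           macrophage phases
    FWT, CAF         wild-type fibroblasts, cancer-associated fibroblasts

CAF remodels the extracellular matrix and excludes killer T cells; the
*immune accessibility index* ``Ia = 1 - tanh(alpha * CAF * Kbr)`` partitions
the shared tumor carrying capacity between the exposed and protected pools,
and residual killing of protected cells is attenuated by the barrier
penetration factor ``exp(-alpha^2 * delta * CAF^2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .core import (
    CELL_STATE,
    MOLECULAR_SPECIES,
    EdgeSpec,
    InvalidParameterError,
    NetworkSpec,
    NodeSpec,
    ParameterSet,
)

__all__ = [
    "CELL_NODES",
    "MOLECULAR_NODES",
    "NODE_ORDER",
    "VARIED_PARAMETERS",
    "AccessibilityParams",
    "accessibility_index",
    "barrier_penetration",
    "partition_capacities",
    "build_hnscc_network",
    "nominal_parameters",
    "initial_state",
    "exemplar_parameters",
]

logger = logging.getLogger(__name__)

CELL_NODES = (
    "C0_E", "C0_P", "Cn_E", "Cn_P", "Cp_E", "Cp_P",
    "TKp", "TKn", "THelp", "TReg", "TEx", "M1", "M2", "FWT", "CAF",
)
MOLECULAR_NODES = ("IL2", "IL8", "IL10", "LIF", "IFNG", "IRF8", "OPN", "ICAM1", "Lac")
NODE_ORDER = CELL_NODES + MOLECULAR_NODES


# ---------------------------------------------------------------------------
# accessibility machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessibilityParams:
    """Barrier hyperparameters: CAF proximity fraction ``alpha`` in [0, 1],
    barrier formation rate ``Kbr``, and barrier width ``delta``."""

    alpha: float
    Kbr: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must be in [0,1], got {self.alpha}")
        if self.Kbr < 0 or self.delta < 0:
            raise InvalidParameterError("Kbr and delta must be nonnegative")


def accessibility_index(acc: AccessibilityParams, caf: float) -> float:
    """Immune accessibility index ``Ia = 1 - tanh(alpha * CAF * Kbr)``.

    ``Ia = 1`` means every tumor cell is reachable by killer T cells;
    ``Ia -> 0`` an impenetrable CAF barrier.  Monotone nonincreasing in the
    CAF population.
    """
    if caf < 0:
        raise InvalidParameterError(f"CAF population must be nonnegative, got {caf}")
    return 1.0 - math.tanh(acc.alpha * caf * acc.Kbr)


def barrier_penetration(fcd: float, acc: AccessibilityParams, caf: float) -> float:
    """Effective kill rate ``fcd * exp(-alpha^2 * delta * CAF^2)`` against
    CAF-protected tumor cells."""
    if fcd < 0 or caf < 0:
        raise InvalidParameterError("fcd and CAF must be nonnegative")
    return fcd * math.exp(-(acc.alpha ** 2) * acc.delta * caf * caf)


def partition_capacities(K_total: float, Ia: float) -> tuple[float, float]:
    """Split a total tumor carrying capacity into (immune-accessible,
    CAF-protected) parts with ``K_IA/K_FP = Ia`` and ``K_IA + K_FP = K_total``.
    """
    if K_total <= 0:
        raise InvalidParameterError(f"K_total must be positive, got {K_total}")
    if not 0.0 <= Ia <= 1.0:
        raise InvalidParameterError(f"Ia must be in [0,1], got {Ia}")
    if Ia == 0.0:
        logger.warning("Ia = 0: degenerate split, all capacity is CAF-protected")
        return 0.0, K_total
    k_ia = K_total * Ia / (1.0 + Ia)
    return k_ia, K_total - k_ia


# ---------------------------------------------------------------------------
# the atlas
# ---------------------------------------------------------------------------


def build_hnscc_network() -> NetworkSpec:
    """Construct the fixed 24-node HNSCC TME interaction atlas.

    Wiring summary (all rates are registry keys, shared between the exposed
    and protected copies of a tumor state):

    * IL-8 gates the stem -> PDL1- transition; IFNg gates PDL1- -> PDL1+.
    * LIF gates the wild-type fibroblast -> CAF conversion; OPN is an
      autocrine proliferation signal for CAF (inhibited upstream by
      M1-secreted IRF8 acting on OPN secretion).
    * CAF boosts tumor, regulatory-T and M2 proliferation by paracrine
      interaction; exhausted T cells exert a pro-tumor paracrine effect.
    * Killer-T proliferation is boosted by IL-2 (autocrine), helper T cells
      and IFNg (antigen sensing); helper-T proliferation by PDL1- tumor cells
      and is inhibited by regulatory T cells.
    * PD1+ and PD1- killer T cells eliminate exposed stem and PDL1- tumor
      cells; lactate inhibits their cytotoxicity.  PD1+ killers convert to
      the exhausted state in the presence of PDL1+ tumor cells and M2
      macrophages.
    * Secretion: tumor -> IL-8/OPN/lactate/LIF, fibroblasts -> LIF,
      CAF -> IL-8/OPN, M2 -> IL-8, killer/helper T -> IL-2/IFNg/ICAM1,
      T cells -> IL-10, M1 -> IRF8.  ICAM1 is a read-out species with no
      downstream target.
    """
    nodes = [
        NodeSpec("C0_E", CELL_STATE, "exposed", "C0"),
        NodeSpec("C0_P", CELL_STATE, "protected", "C0"),
        NodeSpec("Cn_E", CELL_STATE, "exposed", "Cn"),
        NodeSpec("Cn_P", CELL_STATE, "protected", "Cn"),
        NodeSpec("Cp_E", CELL_STATE, "exposed", "Cp"),
        NodeSpec("Cp_P", CELL_STATE, "protected", "Cp"),
    ]
    nodes += [NodeSpec(n, CELL_STATE) for n in CELL_NODES[6:]]
    nodes += [NodeSpec(n, MOLECULAR_SPECIES) for n in MOLECULAR_NODES]

    groups = {
        "tumor": ("C0_E", "C0_P", "Cn_E", "Cn_P", "Cp_E", "Cp_P"),
        "TK": ("TKp", "TKn"),
        "Teff": ("TKp", "TKn", "THelp"),
        "Tlymph": ("TKp", "TKn", "THelp", "TReg"),
    }

    e = []

    # proliferation + death for every cell state
    prolif_keys = {
        "C0_E": ("Kprol_C0", "xmax_tumor"), "C0_P": ("Kprol_C0", "xmax_tumor"),
        "Cn_E": ("Kprol_Cn", "xmax_tumor"), "Cn_P": ("Kprol_Cn", "xmax_tumor"),
        "Cp_E": ("Kprol_Cp", "xmax_tumor"), "Cp_P": ("Kprol_Cp", "xmax_tumor"),
        "TKp": ("Kprol_TK", "xmax_TK"), "TKn": ("Kprol_TK", "xmax_TK"),
        "THelp": ("Kprol_THelp", "xmax_THelp"),
        "TReg": ("Kprol_TReg", "xmax_TReg"),
        "TEx": ("Kprol_TEx", "xmax_TK"),
        "M1": ("Kprol_M1", "xmax_M"), "M2": ("Kprol_M2", "xmax_M"),
        "FWT": ("Kprol_FWT", "xmax_fib"), "CAF": ("Kprol_CAF", "xmax_fib"),
    }
    death_keys = {
        "C0_E": "KD_tum", "C0_P": "KD_tum", "Cn_E": "KD_tum", "Cn_P": "KD_tum",
        "Cp_E": "KD_tum", "Cp_P": "KD_tum", "TKp": "KD_TK", "TKn": "KD_TK",
        "THelp": "KD_THelp", "TReg": "KD_TReg", "TEx": "KD_TEx",
        "M1": "KD_M1", "M2": "KD_M2", "FWT": "KD_FWT", "CAF": "KD_CAF",
    }
    for node in CELL_NODES:
        e.append(EdgeSpec("proliferation", node, parameter_keys=prolif_keys[node]))
        e.append(EdgeSpec("death", node, parameter_keys=(death_keys[node],)))
    for species in MOLECULAR_NODES:
        e.append(EdgeSpec("degradation", species, parameter_keys=("KD_mol",)))

    # cell-state transitions (gated first-order conversions)
    for comp in ("E", "P"):
        e.append(
            EdgeSpec(
                "conversion", f"Cn_{comp}", f"C0_{comp}",
                parameter_keys=("Kconv_C0_Cn",),
                modulators=(("IL8", "V_conv_IL8"),),
            )
        )
        e.append(
            EdgeSpec(
                "conversion", f"Cp_{comp}", f"Cn_{comp}",
                parameter_keys=("Kconv_Cn_Cp",),
                modulators=(("IFNG", "V_conv_IFNG"),),
            )
        )
    e.append(
        EdgeSpec(
            "conversion", "CAF", "FWT",
            parameter_keys=("Kconv_FWT_CAF",),
            modulators=(("LIF", "V_conv_LIF"),),
        )
    )
    e.append(
        EdgeSpec(
            "conversion", "M2", "M1",
            parameter_keys=("Kconv_M1_M2",),
            modulators=(("IL10", "V_conv_IL10"),),
        )
    )
    # exhaustion of PD1+ killers requires PDL1+ tumor cells and M2 macrophages
    e.append(
        EdgeSpec(
            "conversion", "TEx", "TKp",
            parameter_keys=("Kconv_exh",),
            modulators=(("Cp", "V_exh"), ("M2", "V_exh")),
        )
    )

    # paracrine proliferation boosts
    para = [
        ("CAF", "tumor", "CAF_tum"),
        ("TEx", "tumor", "TEx_tum"),
        ("OPN", "CAF", "OPN_CAF"),
        ("CAF", "TReg", "CAF_TReg"),
        ("CAF", "M2", "CAF_M2"),
        ("IL2", "TK", "IL2_TK"),
        ("THelp", "TK", "THelp_TK"),
        ("IFNG", "TK", "IFNG_TK"),
        ("Cn", "THelp", "Cn_THelp"),
    ]
    for src, tgt, tag in para:
        e.append(
            EdgeSpec(
                "paracrine", tgt, src,
                parameter_keys=(f"Kpara_{tag}", f"V_{tag}", f"alpha_{tag}"),
            )
        )

    # regulatory inhibitions
    e.append(
        EdgeSpec(
            "regulatory_inhibition", "THelp", "TReg",
            parameter_keys=("Vreg_TReg_THelp", "alphareg_TReg_THelp"),
            applies_to="proliferation",
        )
    )
    e.append(
        EdgeSpec(
            "regulatory_inhibition", "OPN", "IRF8",
            parameter_keys=("Vreg_IRF8_OPN", "alphareg_IRF8_OPN"),
            applies_to="secretion",
        )
    )
    e.append(
        EdgeSpec(
            "regulatory_inhibition", "TK", "Lac",
            parameter_keys=("Vreg_Lac_kill", "alphareg_Lac_kill"),
            applies_to="elimination",
        )
    )

    # killer-T elimination of exposed, non-PDL1+ tumor cells (the protected
    # copies receive only the barrier-penetration leak, never a direct edge)
    for killer in ("TKp", "TKn"):
        for target in ("C0_E", "Cn_E"):
            e.append(
                EdgeSpec(
                    "elimination", target, killer,
                    parameter_keys=("Kkill", "alpha_ac"),
                )
            )

    # secretion
    secretion = [
        ("tumor", "IL8", "Ksec_IL8_tum"),
        ("CAF", "IL8", "Ksec_IL8_CAF"),
        ("M2", "IL8", "Ksec_IL8_M2"),
        ("tumor", "OPN", "Ksec_OPN_tum"),
        ("CAF", "OPN", "Ksec_OPN_CAF"),
        ("tumor", "Lac", "Ksec_Lac_tum"),
        ("tumor", "LIF", "Ksec_LIF_tum"),
        ("FWT", "LIF", "Ksec_LIF_FWT"),
        ("Teff", "IL2", "Ksec_IL2_T"),
        ("Teff", "IFNG", "Ksec_IFNG_T"),
        ("Teff", "ICAM1", "Ksec_ICAM1_T"),
        ("Tlymph", "IL10", "Ksec_IL10_T"),
        ("M1", "IRF8", "Ksec_IRF8_M1"),
    ]
    for src, tgt, key in secretion:
        e.append(EdgeSpec("secretion", tgt, src, parameter_keys=(key,)))

    network = NetworkSpec(nodes, e, groups=groups, name="hnscc_tme")
    assert network.n_nodes == 24, "HNSCC atlas must have 24 nodes"
    return network


# ---------------------------------------------------------------------------
# nominal registry (91 entries)
# ---------------------------------------------------------------------------

# Units: time in days, populations in cell counts, concentrations in arbitrary
# units.  Magnitudes follow the usual QSP conventions: per-capita growth and
# death O(0.1-1)/day, capacities O(10^3-10^4) cells, cytokine turnover ~1/day.
_NOMINAL: dict[str, float] = {
    # proliferation rates (1/day)
    "Kprol_C0": 0.60, "Kprol_Cn": 0.50, "Kprol_Cp": 0.45,
    "Kprol_TK": 0.40, "Kprol_THelp": 0.35, "Kprol_TReg": 0.25,
    "Kprol_TEx": 0.05, "Kprol_M1": 0.40, "Kprol_M2": 0.05,
    "Kprol_FWT": 0.30, "Kprol_CAF": 0.15,
    # carrying capacities (cells)
    "xmax_tumor": 1.0e4, "xmax_TK": 5.0e3, "xmax_THelp": 2.0e3,
    "xmax_TReg": 1.0e3, "xmax_M": 2.0e3, "xmax_fib": 5.0e3,
    # conversions (1/day) and their gate dissociation constants
    "Kconv_C0_Cn": 0.30, "V_conv_IL8": 5.0,
    "Kconv_Cn_Cp": 0.20, "V_conv_IFNG": 2.0,
    "Kconv_FWT_CAF": 0.10, "V_conv_LIF": 5.0,
    "Kconv_M1_M2": 0.10, "V_conv_IL10": 10.0,
    "Kconv_exh": 0.30, "V_exh": 1.0e3,
    # paracrine triples (gain, dissociation constant, proximity index)
    "Kpara_CAF_tum": 1.5, "V_CAF_tum": 1.0e3, "alpha_CAF_tum": 0.5,
    "Kpara_TEx_tum": 0.5, "V_TEx_tum": 5.0e2, "alpha_TEx_tum": 0.5,
    "Kpara_OPN_CAF": 2.0, "V_OPN_CAF": 20.0, "alpha_OPN_CAF": 1.0,
    "Kpara_CAF_TReg": 1.0, "V_CAF_TReg": 1.0e3, "alpha_CAF_TReg": 0.5,
    "Kpara_CAF_M2": 1.0, "V_CAF_M2": 1.0e3, "alpha_CAF_M2": 0.5,
    "Kpara_IL2_TK": 2.0, "V_IL2_TK": 2.0, "alpha_IL2_TK": 1.0,
    "Kpara_THelp_TK": 1.5, "V_THelp_TK": 5.0e2, "alpha_THelp_TK": 1.0,
    "Kpara_IFNG_TK": 1.0, "V_IFNG_TK": 2.0, "alpha_IFNG_TK": 1.0,
    "Kpara_Cn_THelp": 1.5, "V_Cn_THelp": 1.0e3, "alpha_Cn_THelp": 1.0,
    # regulatory inhibition pairs (dissociation constant, weight)
    "Vreg_TReg_THelp": 1.0, "alphareg_TReg_THelp": 2.0e-3,
    "Vreg_IRF8_OPN": 1.0, "alphareg_IRF8_OPN": 0.2,
    "Vreg_Lac_kill": 1.0, "alphareg_Lac_kill": 0.05,
    # elimination
    "Kkill": 5.0e-4, "alpha_ac": 0.9,
    # death rates (1/day)
    "KD_tum": 0.10, "KD_TK": 0.15, "KD_THelp": 0.12, "KD_TReg": 0.10,
    "KD_TEx": 0.20, "KD_M1": 0.10, "KD_M2": 0.10, "KD_FWT": 0.05,
    "KD_CAF": 0.20,
    # molecular degradation (1/day, shared)
    "KD_mol": 1.0,
    # secretion rates (conc units per cell per day)
    "Ksec_IL8_tum": 1.0e-3, "Ksec_IL8_CAF": 1.0e-3, "Ksec_IL8_M2": 1.0e-3,
    "Ksec_OPN_tum": 2.0e-3, "Ksec_OPN_CAF": 2.0e-4,
    "Ksec_Lac_tum": 1.0e-3,
    "Ksec_LIF_tum": 1.0e-3, "Ksec_LIF_FWT": 1.0e-4,
    "Ksec_IL2_T": 1.0e-3, "Ksec_IFNG_T": 1.0e-3, "Ksec_ICAM1_T": 1.0e-3,
    "Ksec_IL10_T": 1.0e-3, "Ksec_IRF8_M1": 1.0e-3,
    # accessibility hyperparameters
    "alpha_acc": 0.5, "Kbr": 2.0e-4, "delta": 2.0e-7,
    # exposed/protected compartment exchange (1/day)
    "Kmig": 0.1,
    # anti-PD1 intervention (binding rate per unit dose per day, dose)
    "k_bind_pd1": 0.1, "dose_pd1": 0.0,
}


def nominal_parameters() -> ParameterSet:
    """The built-in nominal 91-entry registry for the HNSCC network."""
    params = ParameterSet(_NOMINAL)
    if len(params) != 91:  # registry self-check
        raise AssertionError(f"nominal registry has {len(params)} entries, expected 91")
    return params


# parameters with a direct bearing on proliferation/death/conversion of CAF,
# killer T and tumor cells, plus the accessibility hyperparameters: the
# default varied set for steady-state sweeps (the remaining 63 stay nominal)
VARIED_PARAMETERS: tuple[str, ...] = (
    "Kprol_C0", "Kprol_Cn", "Kprol_Cp", "KD_tum",
    "Kconv_C0_Cn", "Kconv_Cn_Cp", "Kkill",
    "Kpara_CAF_tum", "Kpara_TEx_tum",
    "Kprol_TK", "KD_TK", "Kconv_exh",
    "Kpara_IL2_TK", "Kpara_THelp_TK", "Kpara_IFNG_TK", "Vreg_Lac_kill",
    "Kprol_CAF", "KD_CAF", "Kconv_FWT_CAF", "Kpara_OPN_CAF",
    "Kprol_FWT", "KD_FWT", "Kpara_CAF_TReg",
    "alpha_acc", "Kbr", "delta", "alpha_ac", "Kmig",
)


def initial_state(
    network: NetworkSpec | None = None,
    params: ParameterSet | None = None,
    seed_fraction: float = 0.01,
) -> "np.ndarray":
    """Default initial condition: small seed populations (``seed_fraction``
    of the relevant carrying capacity) for exposed stem tumor cells,
    wild-type fibroblasts, M1 macrophages, PD1+ killer, helper, and
    regulatory T cells; zero elsewhere."""
    import numpy as np

    network = network or build_hnscc_network()
    params = params or nominal_parameters()
    x0 = np.zeros(network.n_nodes)
    seeds = {
        "C0_E": params["xmax_tumor"],
        "FWT": params["xmax_fib"],
        "M1": params["xmax_M"],
        "TKp": params["xmax_TK"],
        "THelp": params["xmax_THelp"],
        "TReg": params["xmax_TReg"],
    }
    for node, cap in seeds.items():
        x0[network.index(node)] = seed_fraction * cap
    return x0


# hand-tuned exemplar parameter regimes per TME subtype; each is a set of
# multiplicative tweaks of the nominal registry (documented in docs/methods.md)
_EXEMPLAR_SCALES: dict[str, dict[str, float]] = {
    # killer T cells die out (low proliferation), CAF thrives -> fibrotic only
    "immune_desert": {"Kprol_TK": 0.1, "Kpara_OPN_CAF": 2.0, "Kprol_CAF": 2.0},
    # both immune and fibrotic axes collapse
    "desert": {"Kprol_TK": 0.125, "Kprol_CAF": 0.2, "Kconv_FWT_CAF": 0.05,
               "Kpara_OPN_CAF": 0.1},
    # immune present, CAF depleted (immune/non-fibrotic)
    "fibro_desert": {"Kprol_CAF": 0.2, "Kconv_FWT_CAF": 0.05,
                     "Kpara_OPN_CAF": 0.1},
    # both present, killer T dominant, tumor suppressed
    "immune_dominated": {"Kprol_TK": 1.5},
    # CAF-rich via a strong OPN autocrine, low accessibility, weakened
    # killer compartment, tumor high
    "fibro_dominated": {"Kpara_OPN_CAF": 3.0, "Kbr": 10.0, "delta": 10.0,
                        "Kprol_TK": 0.5, "Kconv_exh": 3.0},
    # an immune desert held down purely by the killer-T death/proliferation
    # balance, bistable through the IL-2 autocrine loop: the regime of the
    # one-time IL-2 spike experiment (its self-sustain point sits above the
    # killer-T seed population, so only a sufficient spike tips it)
    "il2_reprogrammable_desert": {"Kprol_TK": 0.5, "KD_TK": 1.7,
                                  "Kconv_exh": 0.0, "V_IL2_TK": 0.5,
                                  "Kprol_THelp": 0.3, "Kpara_OPN_CAF": 2.0,
                                  "Kprol_CAF": 2.0},
}


def exemplar_parameters(label: str) -> ParameterSet:
    """A documented representative parameter regime for a TME subtype label."""
    try:
        scales = _EXEMPLAR_SCALES[label]
    except KeyError:
        raise KeyError(
            f"unknown subtype label {label!r}; one of {sorted(_EXEMPLAR_SCALES)}"
        ) from None
    return nominal_parameters().scaled(scales)
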
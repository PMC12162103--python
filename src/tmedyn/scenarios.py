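"""Figure-level in-silico experiments: desert diversity, ICI response by
subtype, IL-2 spike threshold, OPN/LIF knockout, and biomarker read-outs.

Every scenario follows the same treatment protocol: integrate the untreated
model to its pre-therapy steady state; re-seed a small killer-T population
and a trace IL-2 level (a TME is never entirely devoid of circulating
effector cells); apply the intervention; integrate to the post-therapy
steady state.  Reports carry tidy tables plus provenance (parameter hash,
package version, seeds) so every number traces back to a reproducible run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NetworkSpec, ParameterSet
from .hnscc import build_hnscc_network, exemplar_parameters, initial_state
from .interventions import apply_anti_pd1, il2_spike, knockout
from .simulate import SteadyStateRecord, steady_state
from .sweep import ClassifierThresholds, classify_steady_state

__all__ = [
    "ScenarioReport",
    "ici_pre_post",
    "scenario_immune_desert_variants",
    "scenario_ici_by_subtype",
    "scenario_il2_threshold",
    "scenario_opn_lif_knockout",
    "scenario_biomarkers",
]

# treatment-protocol seeds: killer T at 1% of capacity, trace IL-2
KILLER_SEED_FRACTION = 0.01
IL2_FLOOR = 0.1

DEFAULT_DOSE = 5.0
_T_MAX = 3000.0

EXERCISED_SUBTYPES = (
    "immune_desert", "fibro_desert", "immune_dominated", "fibro_dominated",
)


@dataclass
class ScenarioReport:
    """Named tidy tables plus provenance for one scenario run."""

    name: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, table in self.tables.items():
            table.to_csv(out / f"{self.name}_{key}.csv", index=False)


def _provenance(params: ParameterSet, **extra) -> dict:
    from . import __version__
    from .simulate import _params_hash

    return {"params_hash": _params_hash(params), "version": __version__, **extra}


def _seed_immune(x: np.ndarray, network: NetworkSpec, params: ParameterSet) -> np.ndarray:
    out = x.copy()
    i_tk, i_il2 = network.index("TKp"), network.index("IL2")
    out[i_tk] = max(out[i_tk], KILLER_SEED_FRACTION * params["xmax_TK"])
    out[i_il2] = max(out[i_il2], IL2_FLOOR)
    return out


def ici_pre_post(
    network: NetworkSpec,
    params: ParameterSet,
    dose: float,
    *,
    x0: np.ndarray | None = None,
    frozen_ia: float | None = None,
    t_max: float = _T_MAX,
    extra_knockouts: tuple[tuple[str, float], ...] = (),
) -> tuple[SteadyStateRecord, SteadyStateRecord]:
    """Pre- and post-therapy steady states under the standard ICI protocol.

    At ``dose = 0`` the post run is the same model restarted from the seeded
    pre-state (an identity check up to the seeding).  ``extra_knockouts`` are
    (species, fraction) production knockouts applied together with the drug.
    """
    if x0 is None:
        x0 = initial_state(network, params)
    pre = steady_state(network, params, x0, t_max=t_max, frozen_ia=frozen_ia)
    x1 = _seed_immune(pre.state, network, params)
    net2, p2 = apply_anti_pd1(network, params, dose)
    for species, fraction in extra_knockouts:
        net2, p2 = knockout(net2, p2, species, fraction=fraction)
    post = steady_state(net2, p2, x1, t_max=t_max, frozen_ia=frozen_ia)
    return pre, post


def _record_row(rec: SteadyStateRecord, network: NetworkSpec, prefix: str) -> dict:
    row = {
        f"{prefix}_tumor": rec.derived["total_tumor"],
        f"{prefix}_killer_T": rec.derived["killer_T_total"],
        f"{prefix}_CAF": rec.derived["CAF"],
        f"{prefix}_Ia": rec.derived["Ia"],
        f"{prefix}_converged": rec.converged,
    }
    for species in ("IL8", "Lac", "OPN", "LIF", "IL2"):
        row[f"{prefix}_{species}"] = rec.state[network.index(species)]
    return row


# ---------------------------------------------------------------------------
# immune-desert diversity (low-proliferation / exhaustion / Treg variants)
# ---------------------------------------------------------------------------


def _desert_variant(
    pre: SteadyStateRecord, network: NetworkSpec, params: ParameterSet
) -> str:
    """Attribute a killer-T-depleted steady state to its dominant mechanism.

    Exhausted pools decay once their killer-T source is gone, so the
    attribution reads the depreciation *channels* at the pre-therapy state:
    an exhaustion conversion outweighing natural death marks an
    exhaustion-driven desert; a strongly Treg-suppressed helper compartment a
    Treg-driven (immune-cold) one; anything else is low-proliferation.
    """
    if pre.derived["killer_frac"] >= ClassifierThresholds().eps_killer:
        return "immune_present"
    idx = network.index
    cp = pre.state[idx("Cp_E")] + pre.state[idx("Cp_P")]
    m2 = pre.state[idx("M2")]
    v = params["V_exh"]
    exh_drain = params["Kconv_exh"] * cp / (v + cp) * m2 / (v + m2)
    treg_suppression = params["Vreg_TReg_THelp"] / (
        params["Vreg_TReg_THelp"]
        + params["alphareg_TReg_THelp"] * pre.state[idx("TReg")]
    )
    if exh_drain > params["KD_TK"]:
        return "exhaustion_driven"
    if treg_suppression < 0.25:
        return "treg_driven"
    return "low_proliferation"


def scenario_immune_desert_variants(
    base: ParameterSet | None = None,
    prolif_scales: tuple[float, ...] = (0.1, 1.0),
    exhaustion_scales: tuple[float, ...] = (1.0, 30.0),
    caf_treg_scales: tuple[float, ...] = (1.0, 10.0),
    dose: float = DEFAULT_DOSE,
    network: NetworkSpec | None = None,
) -> ScenarioReport:
    """Map the mechanisms behind killer-T depletion and their ICI response.

    Two sub-scans: killer-T proliferation x exhaustion rate, and the
    CAF->Treg axis (paracrine gain and Treg->helper suppression scaled up
    together, with Treg self-proliferation scaled down so Treg abundance is
    genuinely CAF-driven).  Each grid point's pre-therapy steady state is
    labeled and attributed to a low-proliferation, exhaustion-driven, or
    Treg-driven mechanism; anti-PD1 is then applied and the report marks
    which variants respond (killer-T recovery).
    """
    if not (prolif_scales and exhaustion_scales and caf_treg_scales):
        raise ValueError("scan grids must be non-empty")
    network = network or build_hnscc_network()
    base = base or exemplar_parameters("immune_desert").scaled({"Kprol_TK": 10.0})
    # base has nominal killer-T proliferation; the scans scale it down
    points = [
        {"Kprol_TK": ps, "Kconv_exh": es}
        for ps in prolif_scales
        for es in exhaustion_scales
    ]
    # Treg axis: killers here depend on helper-T antigen sensing (weak
    # autocrine gains, sub-critical bare proliferation); Treg abundance is
    # CAF-driven (low self-proliferation, scaled paracrine gain and
    # helper-suppression weight)
    points += [
        {"Kprol_TK": 0.5, "Kpara_IL2_TK": 0.05, "Kpara_IFNG_TK": 0.05,
         "Kprol_TReg": 0.4, "Kpara_CAF_TReg": cs, "alphareg_TReg_THelp": cs}
        for cs in caf_treg_scales
    ]
    rows = []
    for scales in points:
        p = base.scaled(scales)
        pre, post = ici_pre_post(network, p, dose)
        row = {
            "prolif_scale": scales["Kprol_TK"],
            "exhaustion_scale": scales.get("Kconv_exh", 1.0),
            "caf_treg_scale": scales.get("Kpara_CAF_TReg", 1.0),
            "label": classify_steady_state(pre),
            "variant": _desert_variant(pre, network, p),
            "TEx_pre": pre.state[network.index("TEx")],
            "TReg_pre": pre.state[network.index("TReg")],
            "THelp_pre": pre.state[network.index("THelp")],
            "responds": (
                post.derived["killer_T_total"]
                > 1.05 * pre.derived["killer_T_total"] + 10.0
            ),
        }
        row.update(_record_row(pre, network, "pre"))
        row.update(_record_row(post, network, "post"))
        rows.append(row)
    return ScenarioReport(
        name="desert_variants",
        tables={"variants": pd.DataFrame(rows)},
        provenance=_provenance(base, dose=dose),
    )


# ---------------------------------------------------------------------------
# ICI response per subtype
# ---------------------------------------------------------------------------


def scenario_ici_by_subtype(
    representatives: dict[str, ParameterSet] | None = None,
    dose: float = DEFAULT_DOSE,
    *,
    ia_grid: tuple[float, ...] = (0.02, 0.1, 0.3, 0.6, 0.9),
    resource_scales: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0),
    network: NetworkSpec | None = None,
) -> ScenarioReport:
    """Pre/post-therapy compositions for representative parameter regimes of
    each subtype, plus the subtype-specific scans: post-therapy tumor versus
    frozen accessibility for the fibro-dominated regime, and tumor versus
    resource supply (recurrence risk) for the immune/non-fibrotic regime.
    """
    network = network or build_hnscc_network()
    if representatives is None:
        representatives = {
            label: exemplar_parameters(label)
            for label in ("desert",) + EXERCISED_SUBTYPES
        }
    rows = []
    for label, params in representatives.items():
        pre, post = ici_pre_post(network, params, dose)
        row = {"subtype": label, "pre_label": classify_steady_state(pre)}
        row.update(_record_row(pre, network, "pre"))
        row.update(_record_row(post, network, "post"))
        row["caf_reduction"] = pre.derived["CAF"] - post.derived["CAF"]
        rows.append(row)
    tables = {"subtypes": pd.DataFrame(rows)}

    if "fibro_dominated" in representatives:
        p = representatives["fibro_dominated"]
        scan = []
        for ia in ia_grid:
            pre, post = ici_pre_post(network, p, dose, frozen_ia=ia)
            scan.append(
                {"frozen_Ia": ia,
                 "pre_tumor": pre.derived["total_tumor"],
                 "post_tumor": post.derived["total_tumor"],
                 "pre_CAF": pre.derived["CAF"],
                 "post_CAF": post.derived["CAF"]}
            )
        tables["fibro_ia_scan"] = pd.DataFrame(scan)

    if "fibro_desert" in representatives:
        p = representatives["fibro_desert"]
        scan = []
        for rs in resource_scales:
            pr = p.scaled({"xmax_tumor": rs})
            pre, post = ici_pre_post(network, pr, dose)
            scan.append(
                {"resource_scale": rs,
                 "resource_capacity": pr["xmax_tumor"],
                 "pre_tumor": pre.derived["total_tumor"],
                 "post_tumor": post.derived["total_tumor"]}
            )
        tables["resource_scan"] = pd.DataFrame(scan)

    any_params = next(iter(representatives.values()))
    return ScenarioReport(
        name="ici_by_subtype", tables=tables,
        provenance=_provenance(any_params, dose=dose),
    )


# ---------------------------------------------------------------------------
# one-time IL-2 spike threshold
# ---------------------------------------------------------------------------


def scenario_il2_threshold(
    params: ParameterSet | None = None,
    amplitudes: np.ndarray | None = None,
    *,
    rel_tol: float = 0.01,
    network: NetworkSpec | None = None,
) -> ScenarioReport:
    """Locate the one-time IL-2 spike amplitude that tips an immune-desert
    TME into an immune-non-desert steady state.

    Grid scan followed by bisection to ``rel_tol`` relative precision.
    Returns ``inf`` when no amplitude on the grid escapes the desert (the
    IL-2-driven killer-T proliferation gain is below its floor).
    """
    network = network or build_hnscc_network()
    params = params or exemplar_parameters("il2_reprogrammable_desert")
    if amplitudes is None:
        amplitudes = np.logspace(-2, 3, 11)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.max() / max(amplitudes.min(), 1e-300) < 100.0:
        raise ValueError("amplitude grid should span at least two decades")

    pre = steady_state(network, params, initial_state(network, params),
                       t_max=_T_MAX)

    def escapes(amp: float) -> tuple[bool, str, float]:
        x1 = il2_spike(pre.state, amp, network)
        i_tk = network.index("TKp")
        x1[i_tk] = max(x1[i_tk], KILLER_SEED_FRACTION * params["xmax_TK"])
        rec = steady_state(network, params, x1, t_max=_T_MAX)
        label = classify_steady_state(rec)
        return (
            label not in ("desert", "immune_desert", "unlabeled"),
            label,
            rec.derived["killer_T_total"],
        )

    rows = []
    lo, hi = None, None
    prev = 0.0
    for amp in amplitudes:
        out, label, killer = escapes(amp)
        rows.append({"amplitude": amp, "escapes_desert": out, "label": label,
                     "killer_T_final": killer})
        if out and hi is None:
            lo, hi = prev, amp
        prev = amp
    if hi is None:
        threshold = math.inf
    else:
        while lo > 0 and (hi - lo) / hi > rel_tol:
            mid = math.sqrt(lo * hi) if lo > 0 else hi / 2
            out, _, _ = escapes(mid)
            if out:
                hi = mid
            else:
                lo = mid
        threshold = hi
    return ScenarioReport(
        name="il2_threshold",
        tables={"amplitude_scan": pd.DataFrame(rows)},
        thresholds={"il2_spike_amplitude": threshold},
        provenance=_provenance(params),
    )


# ---------------------------------------------------------------------------
# OPN / LIF knockout of the fibro-dominated TME
# ---------------------------------------------------------------------------


def scenario_opn_lif_knockout(
    params: ParameterSet | None = None,
    opn_fractions: np.ndarray | None = None,
    *,
    network: NetworkSpec | None = None,
) -> ScenarioReport:
    """Effect of graded OPN reduction, with and without LIF knockout, on the
    inaccessible/accessible tumor balance and the accessibility index of an
    established fibro-dominated TME.

    Knockouts start from the untreated steady state (treating an existing
    tumor); the threshold OPN fraction is located at the largest gradient of
    the tumor balance.
    """
    network = network or build_hnscc_network()
    params = params or exemplar_parameters("fibro_dominated")
    if opn_fractions is None:
        opn_fractions = np.linspace(0.0, 1.0, 6)
    opn_fractions = np.asarray(opn_fractions, dtype=float)

    base = steady_state(network, params, initial_state(network, params),
                        t_max=_T_MAX)
    exposed = [network.index(c) for c in ("C0_E", "Cn_E", "Cp_E")]
    protected = [network.index(c) for c in ("C0_P", "Cn_P", "Cp_P")]

    rows = []
    for lif_ko in (False, True):
        for fraction in opn_fractions:
            net2, p2 = knockout(network, params, "OPN", fraction=float(fraction))
            if lif_ko:
                net2, p2 = knockout(net2, p2, "LIF", fraction=1.0)
            rec = steady_state(net2, p2, base.state, t_max=_T_MAX)
            t_e = float(sum(rec.state[i] for i in exposed))
            t_p = float(sum(rec.state[i] for i in protected))
            rows.append(
                {"opn_fraction": float(fraction), "lif_knockout": lif_ko,
                 "CAF": rec.derived["CAF"], "Ia": rec.derived["Ia"],
                 "tumor_accessible": t_e, "tumor_protected": t_p,
                 "inaccessible_to_accessible": t_p / max(t_e, 1e-12),
                 "label": classify_steady_state(rec),
                 "converged": rec.converged}
            )
    table = pd.DataFrame(rows)
    with_lif = table[~table["lif_knockout"]].sort_values("opn_fraction")
    ratio = with_lif["inaccessible_to_accessible"].to_numpy()
    frac = with_lif["opn_fraction"].to_numpy()
    if len(frac) > 1:
        grad = np.abs(np.diff(ratio))
        k = int(np.argmax(grad))
        threshold = float(0.5 * (frac[k] + frac[k + 1]))
    else:
        threshold = math.nan
    return ScenarioReport(
        name="opn_lif_knockout",
        tables={"knockout_scan": table},
        thresholds={"opn_fraction": threshold},
        provenance=_provenance(params),
    )


# ---------------------------------------------------------------------------
# biomarker read-outs
# ---------------------------------------------------------------------------


def biomarker_sign(pre: float, post: float, deadband: float = 0.01) -> int:
    """Sign of the post-pre change with a relative deadband (1% default)."""
    if abs(post - pre) <= deadband * max(abs(pre), 1e-12):
        return 0
    return 1 if post > pre else -1


def scenario_biomarkers(
    representatives: dict[str, ParameterSet] | None = None,
    dose: float = DEFAULT_DOSE,
    *,
    network: NetworkSpec | None = None,
) -> ScenarioReport:
    """Pre/post-therapy IL-8 and lactate levels per TME subtype and the sign
    of their change: the candidate-biomarker pattern.  IL-8 stays flat in the
    low-proliferation immune desert (no effector cells, nothing moves), drops
    with the tumor burden in the responsive immune-dominated and
    immune/non-fibrotic subtypes, and creeps up in the CAF-shielded
    fibro-dominated TME (the killer/IL-10/M2 axis adds IL-8 sources while the
    protected tumor persists).
    """
    network = network or build_hnscc_network()
    if representatives is None:
        representatives = {
            label: exemplar_parameters(label) for label in EXERCISED_SUBTYPES
        }
    rows = []
    for label, params in representatives.items():
        pre, post = ici_pre_post(network, params, dose)
        row = {"subtype": label}
        for species in ("IL8", "Lac", "OPN", "LIF", "IL2"):
            a = pre.state[network.index(species)]
            b = post.state[network.index(species)]
            row[f"{species}_pre"] = a
            row[f"{species}_post"] = b
            row[f"{species}_sign"] = biomarker_sign(a, b)
        row["pre_tumor"] = pre.derived["total_tumor"]
        row["post_tumor"] = post.derived["total_tumor"]
        rows.append(row)
    any_params = next(iter(representatives.values()))
    return ScenarioReport(
        name="biomarkers",
        tables={"biomarkers": pd.DataFrame(rows)},
        provenance=_provenance(any_params, dose=dose),
    )
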
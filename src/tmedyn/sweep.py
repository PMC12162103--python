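"""Parameter sweeps, the proliferation/death balance metric, and the
five-way TME-subtype classification of steady states.

The landscape workflow: draw Latin-hypercube samples (on a log scale) of the
parameters with a direct bearing on the proliferation, death and conversion
of CAF, killer T and tumor cells; integrate each sample to steady state;
classify the resulting (killer T, CAF, tumor) composition into one of the
five subtypes observed clinically::

    desert            neither killer T cells nor CAF persist
    immune_desert     CAF persists, killer T cells do not ("fibrotic only")
    fibro_desert      killer T cells persist, CAF does not ("immune/non-fibrotic")
    immune_dominated  both persist, killer-T-skewed composition
    fibro_dominated   both persist, CAF-skewed with a high tumor burden
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .core import NetworkSpec, ParameterSet
from .simulate import SteadyStateRecord, derived_summaries, steady_state

__all__ = [
    "UNLABELED",
    "SUBTYPE_LABELS",
    "SweepDesign",
    "ClassifierThresholds",
    "ClassificationResult",
    "DesignError",
    "default_design",
    "sample_parameters",
    "zeta",
    "classify_steady_state",
    "run_sweep",
    "local_sensitivity",
]

logger = logging.getLogger(__name__)

SUBTYPE_LABELS = (
    "desert",
    "immune_desert",
    "fibro_desert",
    "immune_dominated",
    "fibro_dominated",
)
# synonyms used in the clinical literature
LABEL_SYNONYMS = {
    "immune_desert": "fibrotic only",
    "fibro_desert": "immune/non-fibrotic",
}
UNLABELED = "unlabeled"


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SweepDesign:
    """Which parameters to vary, over which multiplicative ranges.

    ``varied`` maps parameter names to (low, high) multipliers of the base
    value; sampling is Latin hypercube on the log10 scale.  All other
    registry entries stay at their base values.
    """

    varied: dict[str, tuple[float, float]]
    n_samples: int
    seed: int
    base: ParameterSet | None = None

    def __post_init__(self) -> None:
        for name, (low, high) in self.varied.items():
            if low <= 0 or high < low:
                raise DesignError(f"range for {name!r} must satisfy 0 < low <= high")
        if self.n_samples < 0:
            raise DesignError("n_samples must be nonnegative")


def default_design(
    n_samples: int, seed: int, low: float = 0.1, high: float = 10.0
) -> SweepDesign:
    """The standard landscape design: the 28 proliferation/death/conversion
    parameters of CAF, killer T and tumor cells plus the accessibility
    hyperparameters, each over [low x, high x] nominal."""
    from .hnscc import VARIED_PARAMETERS, nominal_parameters

    return SweepDesign(
        varied={p: (low, high) for p in VARIED_PARAMETERS},
        n_samples=n_samples,
        seed=seed,
        base=nominal_parameters(),
    )


def sample_parameters(design: SweepDesign) -> list[ParameterSet]:
    """Latin-hypercube samples on the log10 scale, deterministic under seed.

    Proximity/accessibility fractions (keys starting ``alpha``) are capped at
    1 after scaling, respecting their [0, 1] domain.
    """
    if not design.varied:
        raise DesignError("design varies no parameters")
    base = design.base
    if base is None:
        from .hnscc import nominal_parameters

        base = nominal_parameters()
    names = list(design.varied)
    sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
    unit = sampler.random(design.n_samples)
    out: list[ParameterSet] = []
    for row in unit:
        values = base.to_dict()
        for u, name in zip(row, names):
            low, high = design.varied[name]
            if low == high:
                value = base[name] * low
            else:
                lo = math.log10(base[name] * low)
                hi = math.log10(base[name] * high)
                value = 10.0 ** (lo + u * (hi - lo))
            if name.startswith("alpha"):
                value = min(value, 1.0)
            values[name] = value
        out.append(ParameterSet(values))
    return out


# ---------------------------------------------------------------------------
# zeta: proliferation-to-depreciation balance
# ---------------------------------------------------------------------------


def zeta(cell: str, network: NetworkSpec, params: ParameterSet) -> float:
    """Log balance between the maximum proliferation factor of a cell state
    and the sum of its outgoing kill, conversion, and death rates.

    The maximum proliferation factor is ``Kprol * prod(1 + Kpara)`` over the
    cell's incoming paracrine edges (the paracrine multiplier is bounded above
    by ``1 + Kpara``).  Natural log.  A zero denominator yields ``+inf`` with
    a warning.  For total tumor burden, take the max over tumor cell states.
    """
    node = network.node(cell)
    if node.role != "cell_state":
        raise ValueError(f"{cell!r} is not a cell state")
    prolif = network.edges_into(cell, "proliferation")
    if not prolif:
        raise ValueError(f"{cell!r} has no proliferation flux")
    fmax = params[prolif[0].parameter_keys[0]]
    for edge in network.edges_into(cell, "paracrine"):
        fmax *= 1.0 + params[edge.parameter_keys[0]]

    denom = 0.0
    for edge in network.edges_into(cell, "elimination"):
        denom += params[edge.parameter_keys[0]]
    for edge in network.edges_from(cell, "conversion"):
        denom += math.prod(params[k] for k in edge.parameter_keys)
    for edge in network.edges_into(cell, "death"):
        denom += math.prod(params[k] for k in edge.parameter_keys)
    if denom == 0.0:
        logger.warning("zeta(%s): zero depreciation rate, returning +inf", cell)
        return math.inf
    return math.log(fmax / denom)


def zeta_summary(network: NetworkSpec, params: ParameterSet) -> dict[str, float]:
    """zeta per aggregate cell class: max over tumor states, killer T, CAF."""
    tumor = max(zeta(c, network, params) for c in network.members("tumor"))
    killer = max(zeta(c, network, params) for c in network.members("TK"))
    return {"tumor": tumor, "killer_T": killer, "CAF": zeta("CAF", network, params)}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierThresholds:
    """Presence thresholds as fractions of the respective carrying capacity.

    A population below ``eps`` of its capacity counts as absent; the
    fibro/immune-dominated split additionally requires a tumor burden of at
    least ``tau_tumor`` of capacity on the fibro side.
    """

    eps_killer: float = 0.02
    eps_caf: float = 0.02
    tau_tumor: float = 0.25


def classify_steady_state(
    record: SteadyStateRecord,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Assign exactly one of the five subtype labels to a converged record.

    Non-converged records get the ``unlabeled`` sentinel.
    """
    if not record.converged:
        return UNLABELED
    th = thresholds or ClassifierThresholds()
    killer = record.derived["killer_frac"]
    caf = record.derived["caf_frac"]
    tumor = record.derived["tumor_frac"]
    if killer < th.eps_killer and caf < th.eps_caf:
        return "desert"
    if killer < th.eps_killer:
        return "immune_desert"
    if caf < th.eps_caf:
        return "fibro_desert"
    if caf >= killer and tumor >= th.tau_tumor:
        return "fibro_dominated"
    return "immune_dominated"


@dataclass
class ClassificationResult:
    """Per-sample table plus per-group aggregates of a sweep."""

    samples: pd.DataFrame
    design: SweepDesign
    thresholds: ClassifierThresholds
    records: list[SteadyStateRecord] = field(default_factory=list, repr=False)
    parameter_sets: list[ParameterSet] = field(default_factory=list, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_converged(self) -> int:
        return int(self.samples["converged"].sum())

    def group_counts(self) -> pd.Series:
        return self.samples["label"].value_counts()

    def group_summary(self) -> pd.DataFrame:
        """Median and 25/75% quartiles of tumor, killer T, and CAF per group."""
        rows = []
        for label, sub in self.samples.groupby("label"):
            row: dict[str, float] = {"label": label, "count": len(sub)}
            for col in ("total_tumor", "killer_T_total", "CAF"):
                row[f"{col}_median"] = sub[col].median()
                row[f"{col}_q25"] = sub[col].quantile(0.25)
                row[f"{col}_q75"] = sub[col].quantile(0.75)
            rows.append(row)
        return pd.DataFrame(rows).set_index("label")

    def medoid_params(self, label: str) -> ParameterSet:
        """The group medoid in log-parameter space of the varied entries."""
        mask = self.samples["label"] == label
        if not mask.any():
            raise KeyError(f"no samples labeled {label!r}")
        names = list(self.design.varied)
        values = np.log10(self.samples.loc[mask, names].to_numpy())
        dists = np.abs(values[:, None, :] - values[None, :, :]).sum(axis=(1, 2))
        medoid_pos = int(np.argmin(dists))
        sample_idx = self.samples.index[mask][medoid_pos]
        return self.parameter_sets[sample_idx]


def run_sweep(
    design: SweepDesign,
    *,
    network: NetworkSpec | None = None,
    x0: np.ndarray | None = None,
    thresholds: ClassifierThresholds | None = None,
    t_max: float = 1500.0,
    tol: float = 1e-6,
    window: float = 250.0,
    keep_records: bool = True,
) -> ClassificationResult:
    """Steady state + classification for every sample of a design.

    Fully reproducible under the design seed.  Non-converged samples keep the
    ``unlabeled`` sentinel and are excluded from group statistics.
    """
    from .hnscc import build_hnscc_network, initial_state

    network = network or build_hnscc_network()
    thresholds = thresholds or ClassifierThresholds()
    param_sets = sample_parameters(design) if design.n_samples else []
    names = list(design.varied)
    rows = []
    records: list[SteadyStateRecord] = []
    for i, params in enumerate(param_sets):
        start = x0 if x0 is not None else initial_state(network, params)
        record = steady_state(
            network, params, start, t_max=t_max, tol=tol, window=window
        )
        label = classify_steady_state(record, thresholds)
        row = {"sample": i, "converged": record.converged, "label": label}
        row.update({name: params[name] for name in names})
        for key in ("total_tumor", "killer_T_total", "CAF", "pdl1_ratio", "Ia"):
            row[key] = record.derived[key]
        row.update(
            {f"zeta_{k}": v for k, v in zeta_summary(network, params).items()}
        )
        rows.append(row)
        if keep_records:
            records.append(record)
    columns = (
        ["sample", "converged", "label"]
        + names
        + ["total_tumor", "killer_T_total", "CAF", "pdl1_ratio", "Ia",
           "zeta_tumor", "zeta_killer_T", "zeta_CAF"]
    )
    samples = pd.DataFrame(rows, columns=columns)
    return ClassificationResult(
        samples=samples,
        design=design,
        thresholds=thresholds,
        records=records,
        parameter_sets=param_sets,
    )


# ---------------------------------------------------------------------------
# local sensitivity
# ---------------------------------------------------------------------------


def local_sensitivity(
    network: NetworkSpec,
    params: ParameterSet,
    targets: tuple[str, ...] = ("total_tumor", "killer_T_total", "CAF"),
    parameters: tuple[str, ...] | None = None,
    perturbation: float = 0.05,
    *,
    x0: np.ndarray | None = None,
    t_max: float = 1500.0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """One-at-a-time elasticities ``d log(summary) / d log(param)`` of
    steady-state summaries, by central differences.

    ``targets`` name derived summaries or, for any other string, a node whose
    steady-state value is read directly.  Where a baseline summary is
    (numerically) zero the elasticity is undefined; the signed absolute
    change is reported instead and the ``absolute_change`` flag is set for
    that row.
    """

    def read(rec: SteadyStateRecord, target: str) -> float:
        if target in rec.derived:
            return rec.derived[target]
        return float(rec.state[network.index(target)])

    if perturbation <= 0 or perturbation >= 1:
        raise ValueError("perturbation must be in (0, 1)")
    if parameters is None:
        parameters = tuple(sorted(params))
    if x0 is None:
        from .hnscc import initial_state

        x0 = initial_state(network, params)

    base = steady_state(network, params, x0, t_max=t_max, tol=tol)
    rows = []
    denom = math.log1p(perturbation) - math.log1p(-perturbation)
    for name in parameters:
        if params[name] == 0.0:
            # multiplicative perturbation of an exact zero is a no-op
            rows.append(
                {"parameter": name, "absolute_change": False,
                 **{t: 0.0 for t in targets}}
            )
            continue
        up = steady_state(
            network, params.scaled({name: 1.0 + perturbation}), x0,
            t_max=t_max, tol=tol,
        )
        dn = steady_state(
            network, params.scaled({name: 1.0 - perturbation}), x0,
            t_max=t_max, tol=tol,
        )
        row: dict = {"parameter": name, "absolute_change": False}
        for target in targets:
            b = read(base, target)
            hi, lo = read(up, target), read(dn, target)
            scale = max(abs(b), 1e-9)
            if b <= 1e-9 * max(abs(hi), abs(lo), 1.0) or (
                abs(hi - lo) > 0 and min(hi, lo) <= 0
            ):
                row[target] = hi - lo
                row["absolute_change"] = True
            elif abs(hi - lo) <= 1e-12 * scale:
                row[target] = 0.0
            else:
                row[target] = (math.log(hi) - math.log(lo)) / denom
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
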
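"""Parameter sampling, the zeta balance metric, classification rules, sweep
aggregation, and local sensitivity."""

import math

import numpy as np
import pytest

from tmedyn.core import EdgeSpec, NetworkSpec, NodeSpec, ParameterSet
from tmedyn.hnscc import VARIED_PARAMETERS
from tmedyn.simulate import SteadyStateRecord
from tmedyn.sweep import (
    ClassifierThresholds,
    DesignError,
    SweepDesign,
    UNLABELED,
    classify_steady_state,
    default_design,
    local_sensitivity,
    run_sweep,
    sample_parameters,
    zeta,
)

from conftest import logistic_toy


# ---------------------------------------------------------------------- #
# sampling


def test_sampling_is_deterministic_under_seed(nominal):
    design = default_design(5, seed=7)
    first = [dict(p) for p in sample_parameters(design)]
    second = [dict(p) for p in sample_parameters(design)]
    assert first == second


def test_degenerate_range_returns_nominal(nominal):
    design = SweepDesign(
        varied={p: (1.0, 1.0) for p in VARIED_PARAMETERS},
        n_samples=4, seed=0, base=nominal,
    )
    for sample in sample_parameters(design):
        assert dict(sample) == dict(nominal)


def test_sampled_values_respect_declared_bounds(nominal):
    design = default_design(500, seed=3)
    samples = sample_parameters(design)
    for name, (low, high) in design.varied.items():
        values = np.array([s[name] for s in samples])
        upper = nominal[name] * high
        if name.startswith("alpha"):
            upper = min(upper, 1.0)
        assert values.min() >= nominal[name] * low * (1 - 1e-9)
        assert values.max() <= upper * (1 + 1e-9)


def test_empty_varied_list_is_a_design_error(nominal):
    with pytest.raises(DesignError):
        sample_parameters(SweepDesign(varied={}, n_samples=3, seed=0,
                                      base=nominal))


# ---------------------------------------------------------------------- #
# zeta


def _zeta_toy(kprol=1.0, kpara=None, kd=1.0):
    nodes = [NodeSpec("A", "cell_state"), NodeSpec("B", "cell_state")]
    edges = [
        EdgeSpec("proliferation", "A", parameter_keys=("KprolA", "xmaxA")),
        EdgeSpec("death", "A", parameter_keys=("KDA",)),
        EdgeSpec("proliferation", "B", parameter_keys=("KprolB", "xmaxA")),
        EdgeSpec("death", "B", parameter_keys=("KDB",)),
    ]
    values = {"KprolA": kprol, "xmaxA": 10.0, "KDA": kd,
              "KprolB": 1.0, "KDB": 0.5}
    if kpara is not None:
        edges.append(EdgeSpec("paracrine", "A", "B",
                              parameter_keys=("Kp", "Vp", "ap")))
        values.update({"Kp": kpara, "Vp": 1.0, "ap": 1.0})
    return NetworkSpec(nodes, edges), ParameterSet(values)


def test_zeta_balanced_cell_is_zero():
    net, params = _zeta_toy(kprol=1.0, kd=1.0)
    assert zeta("A", net, params) == pytest.approx(0.0)


def test_zeta_with_paracrine_boost():
    net, params = _zeta_toy(kprol=2.0, kpara=1.0, kd=1.0)
    assert zeta("A", net, params) == pytest.approx(math.log(4.0))


def test_zeta_log_additive_in_proliferation(network, nominal):
    for cell, key in (("TKp", "Kprol_TK"), ("CAF", "Kprol_CAF"),
                      ("C0_E", "Kprol_C0")):
        base = zeta(cell, network, nominal)
        for c in (0.1, 2.0, 10.0):
            scaled = zeta(cell, network, nominal.scaled({key: c}))
            assert scaled - base == pytest.approx(math.log(c), rel=1e-9)


def test_zeta_zero_denominator_is_inf_sentinel():
    net, params = _zeta_toy(kprol=1.0, kd=0.0)
    assert math.isinf(zeta("A", net, params))


def test_zeta_requires_a_cell_state(network, nominal):
    with pytest.raises(ValueError):
        zeta("IL8", network, nominal)


# ---------------------------------------------------------------------- #
# classification


def _record(killer, caf, tumor, converged=True, pdl1=1.0):
    rec = SteadyStateRecord(state=np.zeros(1), converged=converged,
                            residual=0.0, t_final=0.0)
    rec.derived = {"killer_frac": killer, "caf_frac": caf,
                   "tumor_frac": tumor, "pdl1_ratio": pdl1}
    return rec


@pytest.mark.parametrize(
    "killer, caf, tumor, expected",
    [
        (0.0, 0.0, 0.8, "desert"),               # only tumor cells persist
        (0.001, 0.9, 0.9, "immune_desert"),      # fibrotic only
        (0.5, 0.001, 0.3, "fibro_desert"),       # immune/non-fibrotic
        (0.9, 0.5, 0.9, "immune_dominated"),     # killer-skewed
        (0.5, 0.9, 0.9, "fibro_dominated"),      # CAF-skewed, tumor high
        (0.5, 0.9, 0.1, "immune_dominated"),     # CAF-skewed but tumor low
    ],
)
def test_classification_rules(killer, caf, tumor, expected):
    assert classify_steady_state(_record(killer, caf, tumor)) == expected


def test_nonconverged_record_is_unlabeled():
    assert classify_steady_state(_record(0.5, 0.5, 0.5, converged=False)) \
        == UNLABELED


def test_threshold_dataclass_defaults():
    th = ClassifierThresholds()
    assert th.eps_killer == th.eps_caf == 0.02


# ---------------------------------------------------------------------- #
# sweeps


def test_empty_sweep(nominal):
    design = SweepDesign(varied={"Kprol_TK": (0.5, 2.0)}, n_samples=0,
                         seed=0, base=nominal)
    result = run_sweep(design)
    assert result.n_samples == 0
    assert result.group_counts().empty


def test_caf_proliferation_drives_fibrotic_takeover(network, nominal):
    """Along a 1-D scan of the CAF proliferation rate (immune parameters
    fixed favorable), labels move from non-fibrotic groups to
    fibro-dominated."""
    from tmedyn.hnscc import initial_state
    from tmedyn.simulate import steady_state

    labels = []
    for scale in (0.3, 8.0):
        params = nominal.scaled({"Kprol_CAF": scale})
        rec = steady_state(network, params, initial_state(network, params))
        labels.append(classify_steady_state(rec))
    assert labels[0] in ("fibro_desert", "immune_dominated")
    assert labels[-1] == "fibro_dominated"


def test_small_sweep_table_shape_and_reproducibility(nominal):
    design = default_design(6, seed=123)
    a = run_sweep(design, keep_records=False)
    b = run_sweep(design, keep_records=False)
    assert a.samples.equals(b.samples)  # byte-identical result tables
    assert len(a.samples) == 6
    assert a.samples["label"].isin(
        ["desert", "immune_desert", "fibro_desert", "immune_dominated",
         "fibro_dominated", UNLABELED]
    ).all()
    converged = a.samples[a.samples["converged"]]
    assert (converged["label"] != UNLABELED).all()
    summary = a.group_summary()
    assert int(summary["count"].sum()) == 6


def test_medoid_belongs_to_group(nominal):
    design = default_design(12, seed=5)
    result = run_sweep(design)
    counts = result.group_counts()
    label = counts.index[0]
    medoid = result.medoid_params(label)
    assert len(medoid) == 91
    with pytest.raises(KeyError):
        result.medoid_params("nonexistent_group")


# ---------------------------------------------------------------------- #
# local sensitivity


def test_logistic_steady_state_elasticities():
    """For pure logistic growth the steady state equals the capacity: zero
    elasticity to the rate, unit elasticity to the capacity."""
    net, params = logistic_toy(kprol=1.0, xmax=100.0, kd=0.0)
    table = local_sensitivity(
        net, params, targets=("A",), parameters=("Kprol", "xmax"),
        x0=np.array([1.0]),
    )
    assert table.loc["Kprol", "A"] == pytest.approx(0.0, abs=1e-6)
    assert table.loc["xmax", "A"] == pytest.approx(1.0, rel=1e-3)


def test_structurally_disconnected_parameter_has_zero_sensitivity():
    nodes = [NodeSpec("A", "cell_state"), NodeSpec("B", "cell_state")]
    edges = [
        EdgeSpec("proliferation", "A", parameter_keys=("KprolA", "xmaxA")),
        EdgeSpec("death", "A", parameter_keys=("KDA",)),
        EdgeSpec("proliferation", "B", parameter_keys=("KprolB", "xmaxB")),
        EdgeSpec("death", "B", parameter_keys=("KDB",)),
    ]
    net = NetworkSpec(nodes, edges)
    params = ParameterSet({"KprolA": 1.0, "xmaxA": 50.0, "KDA": 0.2,
                           "KprolB": 1.0, "xmaxB": 10.0, "KDB": 0.2})
    table = local_sensitivity(net, params, targets=("A",),
                              parameters=("KprolB", "xmaxB"),
                              x0=np.array([1.0, 1.0]))
    assert table.loc["KprolB", "A"] == pytest.approx(0.0, abs=1e-6)
    assert table.loc["xmaxB", "A"] == pytest.approx(0.0, abs=1e-6)


def test_sensitivity_rejects_bad_perturbation(network, nominal):
    with pytest.raises(ValueError):
        local_sensitivity(network, nominal, perturbation=0.0)
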
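"""Anti-PD1, IL-2 spike, and knockout transformations."""

import numpy as np
import pytest

from tmedyn.core import InvalidParameterError, assemble_rhs
from tmedyn.hnscc import exemplar_parameters, initial_state, nominal_parameters
from tmedyn.interventions import (
    InterventionSpec,
    apply_anti_pd1,
    il2_spike,
    knockout,
)
from tmedyn.simulate import steady_state
from tmedyn.synthetic import random_state


def test_intervention_spec_validation():
    InterventionSpec("anti_pd1", "TKp", 1.0)
    with pytest.raises(ValueError):
        InterventionSpec("mystery", "TKp", 1.0)
    with pytest.raises(InvalidParameterError):
        InterventionSpec("il2_spike", "IL2", -1.0)


def test_zero_dose_is_identity(network, nominal):
    net2, p2 = apply_anti_pd1(network, nominal, dose=0.0)
    rhs0 = assemble_rhs(network, nominal)
    rhs1 = assemble_rhs(net2, p2)
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = random_state(rng, network, nominal)
        np.testing.assert_allclose(rhs0(0.0, x), rhs1(0.0, x), rtol=1e-12,
                                   atol=0.0)


def test_anti_pd1_conversion_conserves_killer_t(network, nominal):
    """The drug-induced flux moves cells between the PD1+ and PD1- killer
    pools without creating or destroying them."""
    net2, p2 = apply_anti_pd1(network, nominal, dose=3.0)
    rhs0 = assemble_rhs(network, nominal)
    rhs1 = assemble_rhs(net2, p2)
    i_tkp, i_tkn = network.index("TKp"), network.index("TKn")
    x = random_state(4, network, nominal)
    # silence the enabled elimination edge (and its protected-pool leak)
    x[network.index("Cp_E")] = 0.0
    x[network.index("Cp_P")] = 0.0
    d0, d1 = rhs0(0.0, x), rhs1(0.0, x)
    delta = d1 - d0
    assert delta[i_tkp] == pytest.approx(-p2["k_bind_pd1"] * 3.0 * x[i_tkp])
    assert delta[i_tkp] + delta[i_tkn] == pytest.approx(0.0, abs=1e-9)
    mask = np.ones(24, bool)
    mask[[i_tkp, i_tkn]] = False
    np.testing.assert_allclose(delta[mask], 0.0, atol=1e-12)


def test_anti_pd1_enables_pdl1_killing(network, nominal):
    net2, p2 = apply_anti_pd1(network, nominal, dose=3.0)
    assert net2.edges_into("Cp_E", "elimination") != ()
    assert network.edges_into("Cp_E", "elimination") == ()


def test_no_killer_cells_means_no_drug_effect(network):
    """With no killer T cells and no IL-2 in play, the treated tumor
    trajectory coincides with the untreated one."""
    params = exemplar_parameters("immune_desert")
    pre = steady_state(network, params, initial_state(network, params))
    assert pre.derived["killer_T_total"] == pytest.approx(0.0, abs=1e-6)
    net2, p2 = apply_anti_pd1(network, params, dose=10.0)
    post = steady_state(net2, p2, pre.state)
    np.testing.assert_allclose(post.state, pre.state, rtol=1e-4, atol=1e-6)


def test_exhaustion_driven_desert_responds_when_binding_beats_exhaustion(
    network, nominal
):
    """Strong PD1 binding rescues an exhaustion-driven desert: the PD1-
    pool escapes the exhaustion conversion entirely."""
    params = nominal.scaled({"Kconv_exh": 30.0})
    pre = steady_state(network, params, initial_state(network, params))
    assert pre.derived["killer_frac"] < 0.02  # exhaustion emptied the pool
    x1 = pre.state.copy()
    x1[network.index("TKp")] = 50.0
    x1[network.index("IL2")] = max(x1[network.index("IL2")], 0.1)
    net2, p2 = apply_anti_pd1(network, params, dose=5.0)  # k_bind*dose = 0.5
    post = steady_state(net2, p2, x1)
    assert post.derived["killer_T_total"] > pre.derived["killer_T_total"] + 100


def test_monotone_dose_response_in_immune_dominated(network):
    params = exemplar_parameters("immune_dominated")
    pre = steady_state(network, params, initial_state(network, params))
    x1 = pre.state.copy()
    x1[network.index("IL2")] = max(x1[network.index("IL2")], 0.1)
    tumors = []
    for dose in (0.0, 0.2, 1.0, 5.0):
        net2, p2 = apply_anti_pd1(network, params, dose)
        post = steady_state(net2, p2, x1)
        tumors.append(post.derived["total_tumor"])
    assert all(b <= a + 1e-6 for a, b in zip(tumors, tumors[1:]))


def test_il2_spike_is_additive_and_local(network):
    x0 = np.arange(24, dtype=float)
    assert np.array_equal(il2_spike(x0, 0.0, network), x0)
    spiked = il2_spike(x0, 2.0, network)
    i = network.index("IL2")
    assert spiked[i] == x0[i] + 2.0
    mask = np.ones(24, bool)
    mask[i] = False
    np.testing.assert_array_equal(spiked[mask], x0[mask])
    assert x0[i] != spiked[i]  # original untouched


def test_knockout_identity_at_zero_fraction(network, nominal):
    net2, p2 = knockout(network, nominal, "OPN", fraction=0.0)
    x = random_state(7, network, nominal)
    np.testing.assert_array_equal(
        assemble_rhs(network, nominal)(0.0, x), assemble_rhs(net2, p2)(0.0, x)
    )


def test_knockout_rejects_cell_states(network, nominal):
    with pytest.raises(InvalidParameterError, match="molecular"):
        knockout(network, nominal, "CAF")


def test_production_knockout_silences_secretion(network, nominal):
    net2, p2 = knockout(network, nominal, "LIF", mode="production_zero",
                        fraction=1.0)
    rhs = assemble_rhs(net2, p2)
    x = random_state(8, network, nominal)
    x[network.index("LIF")] = 0.0
    assert rhs(0.0, x)[network.index("LIF")] == 0.0
    # and the LIF-gated fibroblast conversion carries no flux at LIF = 0
    assert rhs.conversion_fluxes(x)[("FWT", "CAF")] == 0.0


def test_clamp_knockout_suppresses_species(network, nominal):
    net2, p2 = knockout(network, nominal, "Lac", mode="clamp_zero",
                        fraction=1.0)
    rec = steady_state(net2, p2, initial_state(network, nominal))
    baseline = steady_state(network, nominal, initial_state(network, nominal))
    i = network.index("Lac")
    assert rec.state[i] < 1e-2 * baseline.state[i]


def test_caf_monotone_in_opn_retention(network):
    """Steady-state CAF is nondecreasing in the OPN fraction retained."""
    params = exemplar_parameters("fibro_dominated")
    base = steady_state(network, params, initial_state(network, params))
    cafs = []
    for removed in (1.0, 0.6, 0.3, 0.0):  # retained: 0, 0.4, 0.7, 1
        net2, p2 = knockout(network, params, "OPN", fraction=removed)
        rec = steady_state(net2, p2, base.state)
        cafs.append(rec.derived["CAF"])
    assert all(b >= a - 1e-6 for a, b in zip(cafs, cafs[1:]))


def test_opn_lif_double_knockout_frees_the_tme(network):
    """Removing both CAF growth channels collapses the barrier: CAF falls
    below baseline and accessibility strictly improves."""
    params = exemplar_parameters("fibro_dominated")
    base = steady_state(network, params, initial_state(network, params))
    net2, p2 = knockout(network, params, "OPN", fraction=1.0)
    net2, p2 = knockout(net2, p2, "LIF", fraction=1.0)
    rec = steady_state(net2, p2, base.state)
    assert rec.derived["CAF"] < base.derived["CAF"]
    assert rec.derived["Ia"] > base.derived["Ia"]
    assert rec.derived["Ia"] > 0.99  # essentially full accessibility
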
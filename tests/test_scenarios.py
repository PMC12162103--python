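"""Figure-level experiments: desert diversity, subtype-specific ICI
response, IL-2 spike threshold, OPN/LIF knockout, biomarker signatures."""

import math

import numpy as np
import pytest

from tmedyn.hnscc import exemplar_parameters
from tmedyn.scenarios import (
    biomarker_sign,
    scenario_biomarkers,
    scenario_ici_by_subtype,
    scenario_il2_threshold,
    scenario_immune_desert_variants,
    scenario_opn_lif_knockout,
)


@pytest.fixture(scope="module")
def biomarkers():
    return scenario_biomarkers()


@pytest.fixture(scope="module")
def ici_by_subtype():
    return scenario_ici_by_subtype()


@pytest.fixture(scope="module")
def opn_lif():
    return scenario_opn_lif_knockout()


def test_biomarker_sign_deadband():
    assert biomarker_sign(10.0, 10.05) == 0
    assert biomarker_sign(10.0, 11.0) == 1
    assert biomarker_sign(10.0, 9.0) == -1
    assert biomarker_sign(0.0, 0.0) == 0


def test_post_ici_il8_sign_pattern(biomarkers):
    """IL-8 across the four exercised subtypes: unchanged in the
    low-proliferation immune desert, decreased in the responsive
    immune-dominated and immune/non-fibrotic subtypes, slightly increased in
    the fibro-dominated one."""
    table = biomarkers.tables["biomarkers"].set_index("subtype")
    assert table.loc["immune_desert", "IL8_sign"] == 0
    assert table.loc["fibro_desert", "IL8_sign"] == -1
    assert table.loc["immune_dominated", "IL8_sign"] == -1
    assert table.loc["fibro_dominated", "IL8_sign"] == 1


def test_il8_absolute_levels_separate_responsive_subtypes(biomarkers):
    """Immune-dominated and immune/non-fibrotic share the falling IL-8
    trend but differ in absolute level (the fibrotic compartment adds IL-8
    sources)."""
    table = biomarkers.tables["biomarkers"].set_index("subtype")
    assert table.loc["immune_dominated", "IL8_pre"] \
        > 1.2 * table.loc["fibro_desert", "IL8_pre"]


def test_lactate_tracks_response(biomarkers):
    table = biomarkers.tables["biomarkers"].set_index("subtype")
    assert table.loc["immune_dominated", "Lac_sign"] == -1
    assert table.loc["immune_desert", "Lac_sign"] == 0


def test_each_exemplar_lands_in_its_subtype(ici_by_subtype):
    table = ici_by_subtype.tables["subtypes"]
    assert (table["pre_label"] == table["subtype"]).all()


def test_immune_dominated_ici_reduces_caf(ici_by_subtype):
    table = ici_by_subtype.tables["subtypes"].set_index("subtype")
    row = table.loc["immune_dominated"]
    assert row["post_CAF"] < row["pre_CAF"]
    assert row["post_tumor"] < 0.25 * row["pre_tumor"]


def test_fibro_dominated_caf_invariant_under_ici(ici_by_subtype):
    """At low accessibility the post-therapy CAF population stays within 5%
    of its pre-therapy value."""
    table = ici_by_subtype.tables["subtypes"].set_index("subtype")
    row = table.loc["fibro_dominated"]
    assert row["post_CAF"] == pytest.approx(row["pre_CAF"], rel=0.05)
    scan = ici_by_subtype.tables["fibro_ia_scan"]
    low_ia = scan.iloc[0]
    assert low_ia["post_CAF"] == pytest.approx(low_ia["pre_CAF"], rel=0.05)


def test_ici_efficacy_improves_with_accessibility(ici_by_subtype):
    scan = ici_by_subtype.tables["fibro_ia_scan"].sort_values("frozen_Ia")
    post = scan["post_tumor"].to_numpy()
    assert all(b <= a + 1e-6 for a, b in zip(post, post[1:]))


def test_pre_ici_tumor_grows_with_resource_capacity(ici_by_subtype):
    scan = ici_by_subtype.tables["resource_scan"].sort_values("resource_scale")
    pre = scan["pre_tumor"].to_numpy()
    assert all(b > a for a, b in zip(pre, pre[1:]))


def test_desert_variant_mechanisms_and_response():
    report = scenario_immune_desert_variants()
    table = report.tables["variants"]
    variants = set(table["variant"])
    assert {"low_proliferation", "exhaustion_driven",
            "treg_driven"} <= variants
    low = table[table["variant"] == "low_proliferation"]
    assert not low["responds"].any()  # no effector source: ICI is inert
    exhausted = table[
        (table["variant"] == "exhaustion_driven")
        & (table["prolif_scale"] >= 1.0)
    ]
    assert exhausted["responds"].all()  # binding outpaces exhaustion
    treg = table[table["variant"] == "treg_driven"]
    assert (treg["TReg_pre"] > 10 * treg["pre_killer_T"]).all()
    assert (treg["THelp_pre"] < 1.0).all()


def test_il2_threshold_exists_and_separates():
    report = scenario_il2_threshold(
        amplitudes=np.logspace(-1, 2, 4), rel_tol=0.05
    )
    threshold = report.thresholds["il2_spike_amplitude"]
    assert math.isfinite(threshold) and threshold > 0
    scan = report.tables["amplitude_scan"]
    assert not scan[scan["amplitude"] < threshold / 2]["escapes_desert"].any()
    assert scan[scan["amplitude"] > 2 * threshold]["escapes_desert"].all()


def test_il2_threshold_infinite_without_autocrine_gain():
    params = exemplar_parameters("il2_reprogrammable_desert").scaled(
        {"Kpara_IL2_TK": 0.0}
    )
    report = scenario_il2_threshold(
        params, amplitudes=np.logspace(0, 2, 3), rel_tol=0.2
    )
    assert math.isinf(report.thresholds["il2_spike_amplitude"])


def test_il2_threshold_rejects_narrow_grid():
    with pytest.raises(ValueError, match="decades"):
        scenario_il2_threshold(amplitudes=np.array([1.0, 2.0]))


def test_opn_reduction_improves_tumor_balance(opn_lif):
    table = opn_lif.tables["knockout_scan"]
    with_lif = table[~table["lif_knockout"]].sort_values("opn_fraction")
    assert with_lif.iloc[0]["opn_fraction"] == 0.0
    ratio = with_lif["inaccessible_to_accessible"].to_numpy()
    assert ratio[-1] < ratio[0]  # full OPN knockout improves the balance
    ia = with_lif["Ia"].to_numpy()
    assert all(b >= a - 1e-9 for a, b in zip(ia, ia[1:]))
    assert 0.0 <= opn_lif.thresholds["opn_fraction"] <= 1.0


def test_lif_knockout_compounds_opn_reduction(opn_lif):
    """Adding a LIF knockout improves accessibility beyond OPN reduction at
    every grid point, and the double knockout reaches full accessibility."""
    table = opn_lif.tables["knockout_scan"]
    merged = table.pivot_table(index="opn_fraction", columns="lif_knockout",
                               values="Ia")
    assert (merged[True] > merged[False]).all()
    full = table[(table["opn_fraction"] == 1.0) & table["lif_knockout"]]
    assert full["Ia"].iloc[0] > 0.99


def test_lif_only_knockout_is_not_sufficient(network):
    """LIF knockout alone improves accessibility but leaves a CAF-rich,
    non-immune-dominated TME."""
    from tmedyn.hnscc import initial_state
    from tmedyn.interventions import knockout
    from tmedyn.simulate import steady_state
    from tmedyn.sweep import classify_steady_state

    params = exemplar_parameters("fibro_dominated")
    base = steady_state(network, params, initial_state(network, params))
    net2, p2 = knockout(network, params, "LIF", fraction=1.0)
    rec = steady_state(net2, p2, base.state)
    assert rec.derived["Ia"] > base.derived["Ia"]
    assert classify_steady_state(rec) != "immune_dominated"
    assert rec.derived["CAF"] > 0.1 * params["xmax_fib"]


def test_reports_are_reproducible_and_traceable(tmp_path, biomarkers):
    assert "params_hash" in biomarkers.provenance
    assert "version" in biomarkers.provenance
    again = scenario_biomarkers()
    assert again.tables["biomarkers"].equals(biomarkers.tables["biomarkers"])
    biomarkers.write(tmp_path)
    assert (tmp_path / "biomarkers_biomarkers.csv").exists()
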
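# tmedyn

A cell-state ODE model of the head-and-neck squamous cell carcinoma (HNSCC)
tumor microenvironment (TME), for computational tumor immunologists who want
to ask *which compositional balances make a tumor respond to checkpoint
inhibition, and what to target when it doesn't*.

## The model

The TME is represented as 24 coupled state variables: 15 cell states — three
tumor states (stem-like C₀, PDL1⁻, PDL1⁺, each split into a killer-T-exposed
and a CAF-protected compartment), five T-cell states (PD1⁺/PD1⁻ killer,
helper, regulatory, exhausted), M1/M2 macrophages, wild-type fibroblasts and
cancer-associated fibroblasts (CAF) — plus nine secreted species (IL-2,
IL-8, IL-10, LIF, IFNγ, IRF8, OPN, ICAM1, lactate). Dynamics are assembled
from typed flux rules:

- proliferation: logistic, `K_prol · x · (1 − x/x_max)`
- cell-state conversion: first order, `K_conv · x_src`, optionally gated by
  promoter occupancy `m/(V + m)`
- paracrine promotion: bounded multiplier `1 + K_para · α · x_i/(V + a·x_i)`
  on the target's proliferation
- regulatory inhibition: factor `1/(V_reg + α · x_i)`
- killer-T elimination: `K_kill · α_ac · x_target · x_killer`
- death/degradation: first order

CAF remodels the extracellular matrix and excludes killer T cells. The
**immune accessibility index** `I_a = 1 − tanh(α · CAF · K_br)` partitions
the tumor carrying capacity between exposed and protected pools
(`K_IA/K_FP = I_a`), and elimination leaks into the protected pool only at
the barrier-penetration rate `exp(−α² δ CAF²)`. The full HNSCC registry has
exactly 91 parameters (time in days; populations in cells; concentrations in
arbitrary units).

On top of the simulator the package provides:

- steady-state detection and **five-way TME subtype classification**
  (desert, immune desert/fibrotic-only, fibro desert/immune-non-fibrotic,
  immune-dominated, fibro-dominated) over Latin-hypercube parameter sweeps;
- the ζ balance metric, `ζ = log(K_prol ∏(1+K_para) / (ΣK_kill + ΣK_conv + K_D))`;
- in-silico interventions: anti-PD1 (drug-driven PD1⁺→PD1⁻ killer-T
  conversion plus PDL1⁺ recognition), one-time IL-2 spikes, and
  production/clamp knockouts of OPN, LIF, lactate or any species;
- figure-level scenario runners (immune-desert diversity, ICI response per
  subtype, IL-2 spike threshold, OPN+LIF knockout, IL-8/lactate biomarkers)
  and one-at-a-time local sensitivity analysis.

## Worked example

```python
from tmedyn import (build_hnscc_network, nominal_parameters, initial_state,
                    steady_state, apply_anti_pd1, classify_steady_state)

net = build_hnscc_network()
params = nominal_parameters()          # 91-entry registry
pre = steady_state(net, params, initial_state(net, params))
print(classify_steady_state(pre))
print(pre.derived["total_tumor"], pre.derived["killer_T_total"],
      pre.derived["CAF"], pre.derived["Ia"])

x1 = pre.state.copy()
x1[net.index("IL2")] = max(x1[net.index("IL2")], 0.1)  # trace IL-2
net_rx, params_rx = apply_anti_pd1(net, params, dose=5.0)
post = steady_state(net_rx, params_rx, x1)
print(post.derived["total_tumor"], post.derived["killer_T_total"],
      post.derived["CAF"])
```

prints (rounded):

```
immune_dominated
tumor 8769   killer T 4493   CAF 2705   Ia 0.74
post-ICI: tumor 0   killer T 9350   CAF 478
```

Untreated, the nominal TME settles into an immune-dominated composition:
the tumor persists near capacity because PDL1⁺ cells escape killing, killer
T cells are abundant, and a moderate CAF pool leaves the TME largely
accessible (I_a ≈ 0.74). Anti-PD1 converts killer T cells to the PD1⁻ state
that recognizes PDL1⁺ tumor cells: the tumor is cleared, and the CAF pool —
deprived of tumor-derived OPN and LIF — collapses by ~80%.

The same experiments are scriptable from the shell via the `tme-dyn` CLI
(`network`, `simulate`, `intervene`, `sweep`, `sensitivity`, `scenario`);
see `tme-dyn --help`.

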
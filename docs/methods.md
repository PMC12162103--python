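# Methods

## Model

The tumor microenvironment is modeled as a spatially homogeneous dynamical
system: 15 cell-state populations and 9 molecular concentrations evolving
under ordinary differential equations. Each cell type contributes its
functionally distinct states rather than a single pooled population — the
level at which immune escape (PDL1 induction), exhaustion, and fibroblast
activation actually operate — while staying far below the dimensionality of
a gene-regulatory description.

Per-node dynamics are sums of typed fluxes:

| rule | form | notes |
|---|---|---|
| proliferation | `K_prol x (1 − x/x_max)` | logistic self-limitation |
| conversion | `K_conv x_src · Π m/(V+m)` | first order; optional saturating gates by promoter species |
| paracrine | `× [1 + K_para α x_i/(V + a x_i)]` | bounded multiplier on the target's proliferation; `a = 1` throughout |
| regulatory inhibition | `× 1/(V_reg + α x_i)` | on proliferation, secretion, or elimination |
| elimination | `K_kill α_ac x_target x_killer` | removed from the target only |
| death / degradation | `K_D x` | every cell state and species |
| secretion | `K_sec x_cell` | first order in each secreting state |

Conversions that require co-factors (the stem→PDL1⁻ transition needs IL-8,
PDL1⁻→PDL1⁺ needs IFNγ, fibroblast→CAF needs LIF, M1→M2 needs IL-10, and
killer-T exhaustion needs both PDL1⁺ tumor cells and M2 macrophages) keep
the first-order backbone and multiply saturating occupancy gates
`m/(V + m)`; the exhaustion gates share one dissociation constant. Molecular
species follow `d[m]/dt = Σ K_sec·x_cell·(optional regulatory factor) −
K_D·[m]`; IRF8 inhibits OPN secretion, lactate inhibits killer-T
cytotoxicity, regulatory T cells inhibit helper-T proliferation. ICAM1 is
secreted by effector T cells and read out only; it feeds back on nothing.
Among the interleukin-6 family signals, LIF carries the
fibroblast-activation role and IL-10 the macrophage-polarization role; the
nine species are IL-2, IL-8, IL-10, LIF, IFNγ, IRF8, OPN, ICAM1 and
lactate.

### CAF barrier and compartments

Each tumor state has an *exposed* and a *protected* copy. The immune
accessibility index `I_a = 1 − tanh(α·CAF·K_br)` is recomputed from the
instantaneous CAF population at every evaluation (or frozen at a constant
for accessibility scans) and partitions the shared tumor carrying capacity:
`K_IA = K·I_a/(1+I_a)`, `K_FP = K/(1+I_a)`, so `K_IA/K_FP = I_a` and the
total is conserved. Elimination edges only target exposed cells; the
assembler automatically applies each one to the protected partner scaled by
the barrier penetration factor `exp(−α²δ·CAF²)` (exponent read as
α-squared, δ-linear, CAF-squared; the factor is pluggable if a different
grouping is preferred). The copies exchange by first-order migration —
exposed→protected at `K_mig(1−I_a)`, protected→exposed at `K_mig·I_a` — an
autonomous scheme under which CAF growth shifts tumor cells into the
protected pool without the right-hand side referencing its own time
derivative. Tumor compartments share one capacity (`x_max_tumor`), which is
also the resource-competition coupling: all six compartments compete for
the same holding capacity.

### Parameters and units

Time is in days, populations in cells, concentrations in arbitrary units
(the model's conclusions are about balances, not absolute titers). The full
registry has exactly 91 entries — 11 proliferation rates, 6 carrying
capacities, 10 conversion entries (5 rates + 5 gate constants), 9 paracrine
triples (gain, dissociation constant, proximity index), 3 regulatory pairs,
2 elimination entries, 9 cell death rates, 1 shared molecular degradation
rate, 13 secretion rates, 3 barrier hyperparameters, 1 compartment-exchange
rate, and 2 anti-PD1 entries (binding rate, dose; dose is 0 untreated) —
and `nominal_parameters()` self-checks that count. Nominal magnitudes
follow common quantitative-systems-pharmacology conventions: per-capita
growth and death of order 0.1–1/day, capacities of order 10³–10⁴ cells,
cytokine turnover ~1/day, secretion scaled so species sit at order 1–20
units at typical cell numbers. Within those scales the couplings are set so
that the qualitative regimes coexist: CAF is sustained mainly by
tumor-derived OPN (autocrine gain) and LIF-gated conversion rather than
raw self-proliferation, so fibrosis tracks the tumor compartment; M2
macrophages are sustained by IL-10-gated conversion from a robust M1 pool,
so the M2 pool has headroom to grow when effector-T-cell-derived IL-10
rises.

## Simulation and steady states

Integration uses SciPy's stiff-capable variable-step solvers (LSODA
default, BDF available) at rtol 1e−6 / atol 1e−9. Numerical guards, chosen
for stiff runs near extinction boundaries:

- fluxes are evaluated on the nonnegative part of the state, and negative
  excursions are pulled back at unit rate (for x < 0 a logistic term is
  destabilizing);
- final trajectories clip residual overshoot in [−1e−6, 0) to zero and
  raise on anything more negative;
- `I_a` is floored at 1e−9 (tanh saturates to exactly 1 in floats at large
  CAF) and the pooled crowding term `x/K` is capped at 101, so a collapsed
  pool decays at a fast but bounded per-capita rate;
- steady states are detected by windowed integration (100-day windows,
  250-day in sweeps) until `max|dx/dt| < 1e−6`/day or `t_max` (2000 days
  default; 1500 in sweeps, 3000 in scenario runs). Non-convergence is
  reported as a flag, never an exception; non-converged samples are
  excluded from group statistics and counted separately.

Tolerance halving moves nominal steady-state summaries by <0.1%, and LSODA
and BDF agree on randomized registries (both under test).

## Sweeps and classification

The landscape sweep varies the 28 parameters with a direct bearing on the
proliferation, death and conversion fluxes of CAF, killer T and tumor cells
plus the accessibility hyperparameters, each over [0.1×, 10×] nominal,
Latin-hypercube sampled on the log10 scale (α-like fractions capped at 1);
the remaining 63 entries stay nominal. Default initial conditions seed 1%
of capacity in exposed stem tumor cells, wild-type fibroblasts, M1
macrophages, PD1⁺ killer, helper and regulatory T cells.

Steady states are classified by rules on capacity-normalized killer-T, CAF
and tumor levels: below ε = 2% of capacity counts as absent; two absent
axes give *desert*, an absent immune (fibrotic) axis gives *immune desert*
(*fibro desert* conversely), and when both persist the composition is
*fibro-dominated* if the CAF fraction is at least the killer fraction and
the tumor burden is at least τ = 25% of capacity, else *immune-dominated*.
The thresholds are deliberate, documented choices; perturbing them ±20%
relabels <10% of a 1000-sample sweep (under test). The PDL1⁻/PDL1⁺ ratio is
carried as a biomarker read-out (immune-dominated states are strongly
PDL1⁺-skewed) rather than as a classification input. ζ uses the natural
log.

## Interventions

The standard treatment protocol runs everywhere: integrate untreated to
steady state, re-seed killer T at 1% of capacity and IL-2 at a 0.1-unit
floor (a TME is never entirely devoid of circulating effectors), apply the
intervention, integrate again. Anti-PD1 is a parameterized conversion
TKp→TKn at rate `k_bind·dose` (constant-dose mode; no pharmacokinetics)
plus a TKn elimination edge against exposed PDL1⁺ tumor cells; TKn carries
no PD1 program and is therefore exhaustion-immune. By default the drug only
converts; an option additionally scales the residual exhaustion rate.
Dose 0 returns the untreated model exactly. Knockouts default to
`production_zero` (all secretion of the species scaled by 1−fraction),
which is what graded "reduction" scans mean; `clamp_zero` attaches a fast
absorbing sink and is exact only for full knockouts. Knockout scans start
from the established untreated steady state — the zero-CAF state is itself
a fixed point, so starting a LIF-knockout run from scratch would trivially
never seed CAF.

## Scenario regimes

Representative parameter regimes per subtype are documented multiplicative
tweaks of the nominal registry (`exemplar_parameters`): e.g. the
fibro-dominated regime strengthens the OPN autocrine gain and the barrier
hyperparameters and weakens the killer compartment; the immune-desert
regime suppresses killer-T proliferation below viability. A seeded-sweep
medoid per group is available (`ClassificationResult.medoid_params`) for
analyses that prefer data-derived representatives. The IL-2-spike regime is
built to be genuinely bistable in the killer-T/IL-2 autocrine loop, with
the self-sustain point above the killer-T seed so only a sufficiently large
one-time spike tips it; with the autocrine gain removed no amplitude
escapes, and the threshold search reports an infinity sentinel.
Mechanism attribution for killer-depleted states reads the depreciation
channels (exhaustion conversion vs natural death vs Treg-suppressed helper
boost) rather than the final exhausted-cell count, because exhausted pools
decay once their killer-T source is gone.

## Synthetic fixtures

The test generator jitters every nonzero registry entry log-normally (0.3
decades), capping fractions at 1, and draws initial states uniformly below
the relevant capacities. It emulates parameter uncertainty around one
structurally fixed network; it does not emulate structural uncertainty,
measurement noise, spatial heterogeneity, or patient-to-patient covariance
of parameters — passing tests certify the simulator and its qualitative
regime structure, not calibration to any cohort.

## Problem sizes

The bundled analyses use a 1000-sample landscape sweep, 100 random draws
for the right-hand-side oracle comparison, 200 draws for the fixture
integration check, six-point knockout grids, and threshold bisection to
1–5% relative precision; all were chosen as the smallest designs that make
the group structure and sign patterns unambiguous.

## Known limitations

Deterministic ODE semantics only (no stochastic or spatial variant); no
parameter estimation from data; molecular species share one degradation
rate; the exposed/protected exchange is a two-pool caricature of spatial
exclusion; exhausted T cells are modeled as a single pro-tumor state; the
resource-competition reading of the shared tumor capacity means post-ICI
recurrence thresholds reflect capacity, not nutrient kinetics — in the
bundled immune/non-fibrotic regime the treated system clears the tumor
across the scanned resource range, and recurrence appears only when
cytotoxicity parameters are weakened. HPV status, tumor staging and B-cell
states are outside the model's scope.
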
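# Methods

## Model structure and assumptions

The kinetic model describes anaerobic batch fermentation of a defined
(synthetic-must-like) medium by a single yeast population. Its central
assumptions:

- **Nitrogen limits growth.** Primary growth is driven entirely by
  assimilation of ammonium and 18 amino acids (proline is not catabolised
  anaerobically). Uptake of each source follows generalized mass action,
  d[AA_i]/dt = −lag(t) · k_i · [AA_i] · X_P, gated by the Baranyi–Roberts
  lag factor; the volumetric growth rate is the nitrogen-weighted sum
  μ_N = −14.0067 · Σ (NN_i/MW_i) · d[AA_i]/dt · Y_{x/N}. The sign
  convention makes μ_N ≥ 0 for consumptive (negative) uptake rates.
- **μ_N and μ_C are volumetric rates** (g L⁻¹ h⁻¹), not specific rates:
  the biomass-component balances are dimensionally volumetric. The
  specific growth rate μ = (dX/dt)/X is computed separately where the
  flux layer needs it.
- **Biomass is a three-component pool** with fixed synthesis fractions
  λ_C = 0.29, λ_P = 0.59, 1 − λ_C − λ_P = 0.12 (nitrogen-limited yeast
  composition from the literature). Total dry weight X is always the
  derived sum — it is never integrated as an independent state, although
  the aggregate balance dX/dt = dX_C + dX_P + dX_mRNA is counted as one of
  the model's 41 equations.
- **Sugar uptake is Michaelis–Menten in each hexose**, scaled by protein
  biomass and amplified by (1 + α·μ_N) (transporter induction during
  growth, applied exactly as written, without saturation). Sucrose, when
  present, hydrolyses first-order and feeds half its mass into each
  hexose; no hydration-mass correction is applied (a documented modelling
  convention). Product formation terms use the *net* hexose derivative,
  so a medium in which hydrolysis transiently outruns uptake would
  transiently reverse product signs; the shipped conditions are
  sucrose-free or keep uptake dominant.
- **Phase transitions are smooth.** φ_N,S = ks_C/(YAN + ks_C) and
  φ_Sugar = ks_S/(Glx + F + ks_S) rise from ≈0 to 1 as nitrogen and sugar
  deplete; the regulatory state G_N,S relaxes toward their product at
  rate τ_G (first-order, so with the product frozen at c, G_N,S → c
  exponentially). Secondary growth is a proportional controller pulling
  the carbohydrate fraction X_C/X toward the set point Θ_C, active only
  under nitrogen starvation.
- **Decay is off by default** (k_D = 0): the parsimonious model has no
  ethanol-driven decay. When k_D > 0 the decay modifier φ_ED — whose
  functional form is this package's own choice, as only its role is
  specified upstream — is a logistic switch in ethanol concentration
  (midpoint 80 g/L, steepness 0.2 L/g).
- **Product variants.** Ethanol is proportional to sugar uptake;
  glycerol, acetate and lactate decline with regulation (× (1 − G_N,S));
  succinate, ethyl acetate, isoamyl acetate and isobutanol are delayed
  until nitrogen depletion (× φ_N,S); phenyl ethyl acetate, 2-phenyl
  ethanol and 2,3-butanediol are additionally repressed in stationary
  phase. Isoamyl alcohol is assigned the nitrogen-delayed class (it is
  the same chemical family as isobutanol); ethyl acetate defaults to
  nitrogen-delayed but is selectable by calibration, as is every variant.
  The acetate equation carries a must-type switch δ (1 synthetic,
  0 natural with a consumption branch); malate is consumed by mass
  action.

### Phase identification

Thresholds (all configurable): lag ends when the lag factor reaches 0.99;
growth ends when YAN ≤ 1e-4 gN/L; the gng transition ends when dX/dt ≤
1e-6 gDW/(L·h); detection degrades gracefully (boundary = final time plus
a warning flag) when a trajectory never crosses a threshold.

## Calibration

The cost is the weighted residual sum Σ_d (y_d − y_m)²/σ_d² over
per-(observable, time) replicate means. σ_d is the replicate standard
deviation floored at 5% of the observable's maximum (replicate spread can
be zero at a single sampling time). The optimizer is a seeded Latin
hypercube multistart over box bounds with local bounded trust-region
least squares in unit-normalized parameter space — a deterministic
scatter-search-style hybrid. Integration failures at candidate parameters
return a large penalized cost so the global search continues.

Which parameters are estimated is explicit per configuration. In the
sucrose-bearing reference configuration, 46 parameters are estimable;
fixed are λ_C, λ_P and Θ_C (biomass-composition literature), μ_maxN
(measured directly from exponential-phase cell counts, standard
Baranyi-model practice), k_D = 0, and the structural switch δ.

Confidence intervals use the Cramér–Rao bound: F = JᵀJ from central
finite-difference residual sensitivities (relative step 1e-5), C = F⁻¹
(pseudo-inverse with a warning when F is numerically singular, cond >
1e12), half-width t_{α/2,γ} √C_ii with γ = N_d − η. Goodness of fit is
per-observable R² on replicate means; zero-variance observables are
reported as missing. Production-law variants are chosen by refitting each
candidate and comparing AIC, ties broken toward the un-repressed form.
Calibration never invokes the flux layer: the kinetic fit alone fixes the
dFBA constraints.

## Flux layer

Exchange bounds at time t: v = (d[compound]/dt)/(MW · X(t)) · 1000 in
mmol/(gDW·h) (the division by biomass is required dimensionally), set as
equalities except for the noisy-measurement compounds (histidine,
succinate, lactate, malate, isobutanol, isoamyl alcohol, 2-phenyl
acetate, 2-phenylethanol), whose bound toward zero is relaxed while the
direction is preserved. The biomass reaction is pinned to (dX/dt)/X,
equality in all phases, with a relaxation ladder as fallback: on
infeasibility, inequality bounds are widened by 1.5×, then equality
bounds opened to a ±5% band, every relaxation logged. Oxygen exchange is
closed (anaerobic).

GAM = GAM_b·μ + Σ c_class · (class synthesis rate per gDW), GAM_b = 30
mmol/gDW, polymerization coefficients c_prot = 39.1, c_RNA = 7.5,
c_carbs = 12.3 mmol ATP per g (literature-style yeast values shipped as
configuration data); the total enters as the ATP-maintenance lower bound
at each step.

The objective weights are (1 − φ_N,S) on ATP hydrolysis and φ_N,S on
protein synthesis, continuous in time; per-term scale factors default
to 1 (the two terms have comparable magnitudes on the shipped network).
pFBA is two-stage: maximize the weighted objective, then fix it at
≥ (1 − 1e-6) of the optimum and minimize Σ|v| with split
positive/negative variables. LPs are solved with HiGHS at 1e-10
feasibility tolerances so optima agree with exact vertex arithmetic to
~1e-10. FVA at the same optimality fraction serves as a variability
sanity check. The default output grid is uniform 0.5 h; the kinetic
solution is interpolated linearly (the stored grid is dense enough that
interpolation error is far below integration tolerance).

Flux scores integrate v_r · DW by the trapezoid rule over a phase,
normalized by total hexose consumption (× 100); DW is carried in gDW/L
since the constant broth volume cancels in the ratio. NFS divides by
phase duration. Note a direct consequence of the definition: with
constant fluxes FS is duration-invariant (numerator and denominator scale
together) and NFS scales as 1/duration. In the differential filter
|log10|S1/S2|| ≥ threshold (default 1e-3), one-sided zero scores count as
infinitely different (included) and double zeros as identical (excluded).

## The toy network

A deterministic 25-reaction anaerobic stand-in for a genome-scale yeast
reconstruction: lumped glycolysis (glc → 2 pyr + 2 ATP + 2 NADH),
ethanol/acetate/succinate/2,3-butanediol branches from pyruvate, glycerol
as the canonical NADH valve, a butanediol route that is a *net* NADH sink
per glucose, cofactor-free overflow sinks so every kinetically pinned
bound combination stays closable, and amino-acid/protein/carbohydrate/RNA
syntheses feeding a biomass pseudo-reaction with composition 0.59/0.29/
0.12 g/gDW. Synthesis reactions carry only small activation ATP costs
because polymerization costs are charged through the GAM decomposition
(no double counting). Every carbon-transforming reaction is
carbon-balanced. The network is small enough that each pFBA sub-problem
is verifiable by exhaustive enumeration of the basic feasible points
(including the |v| kink hyperplanes and the optimality-floor facet).

## Synthetic data generator

The generator reproduces the sampling structure of a bioreactor
campaign: five to seven sampling times spanning lag to stationary
(default seven: 0, 12, 24, 48, 96, 150, 220 h), three biological
replicates, multiplicative Gaussian noise with per-observable CV
(default 5%, truncated at zero — chromatography error scales roughly
with signal and concentrations are nonnegative), fully deterministic
given the seed (NumPy PCG64). The default initial condition mimics a
synthetic must: 100 g/L each of glucose and fructose, 0.3 gN/L of YAN
(40% as ammonium, the rest split equally as nitrogen over the amino
acids), 0.02 gDW/L inoculum.

Preset profiles are qualitative species archetypes — "fast" (reference),
"slow" (slow fructose uptake, succinate-prone), "high_glycerol"
(cryotolerant-style) — with magnitudes typical of wine fermentations at
20–25 °C (ethanol yield 0.42 g/g, ~84 g/L final ethanol, 2.2 gDW/L final
biomass, nitrogen depleted near 80 h, fermentation ~220 h). The fixture
bundle (trajectory + toy network + compound map) was designed so that
every dFBA step is feasible without relaxation: the kinetic biomass yield
on sugar is consistent with fermentative ATP stoichiometry plus the GAM
demand, and residual sugar stays positive through the stationary phase so
phase-wise flux scores are well defined.

What the generator does *not* emulate: correlated residuals, batch
effects between replicates, measurement limits of detection,
temperature or oxygen dynamics, and the species-specific parameter
values of real strains. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated noise model,
not field performance on real campaigns.

## Numerical choices

- Integration: LSODA (stiffness-switching), rtol 1e-8 / atol 1e-10 by
  default; derivatives stored with the trajectory are RHS re-evaluations
  at the stored states. Substrate concentrations are clipped at zero
  *inside rate laws only*, preserving solver smoothness rather than
  clipping the integrator state.
- Test and acceptance problem sizes: a 101-point dFBA grid over 220 h,
  25 oracle LP instances, 10 conservation parameter draws, and a
  recovery fit with 5 free parameters at 7×3 sampling — sizes chosen so
  the whole suite runs in well under a minute on one core while
  exercising every code path at meaningful scale.
- The LP vertex cross-checks and the brute-force rate-law oracle live in
  the test suite, independent of the implementation code paths.

## Known limitations

- Ethanol-inhibition kinetics, temperature dependence, oxygen dynamics
  and proline assimilation are out of scope by design.
- The two-stage pFBA returns one minimal-‖·‖₁ solution; where the
  minimizer is non-unique the reported fluxes depend on the LP solver's
  tie-breaking (FVA quantifies the residual freedom).
- The relaxation ladder trades constraint fidelity for feasibility under
  noisy bounds; every relaxation is logged in the flux trajectory so
  affected steps are identifiable downstream.
- Feedback-coupled dFBA (fluxes driving the kinetics) is deliberately
  not supported — decoupling is the architectural point of the model.
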
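# Methods

## Model structure and assumptions

The simulator follows a single well-mixed *Aedes aegypti* population
structured by life stage (juvenile, adult female, adult male) and by
genotype at two unlinked autosomal loci: the female-killing locus (alleles
K/k) and the antipathogen locus (A/a). The nine two-locus genotypes are
indexed 1..9 in the fixed order KKAA, KkAA, kkAA, KKAa, KkAa, kkAa, KKaa,
Kkaa, kkaa; every array in the package uses this order, and the inheritance
tensor, fitness and viability vectors are built from the same constant to
avoid silent permutation bugs.

Assumptions:

* **Random mating, Mendelian inheritance.** A female's mate genotype is
  drawn in proportion to male genotype frequencies; offspring genotype
  probabilities are products of per-locus Mendelian terms (the loci are
  unlinked and treated as independent). When no males are present the
  mating frequency is undefined and the birth rate is set to zero.
* **Implicit egg stage.** Egg production and hatching are folded into a
  single larval-production rate λ per female; fitness costs multiply this
  rate via w_i, i.e. they act on the fraction of eggs surviving to the
  larval stage. Costs are additive within a locus (heterozygotes pay half
  the homozygous cost) and multiplicative across loci. The closed form
  w_i = (1 − (k_i/2)c_K)(1 − (a_i/2)c_A) is implemented rather than a
  9-entry lookup so dominant/recessive variants can be added later; a unit
  test pins it to the literal per-genotype expressions.
* **Dominant female-specific lethality.** Females carrying any K copy die
  before emergence (γ_i = 0); males are unaffected. Adult K-carrying
  females can still be *released*, because the lethal element is repressed
  during rearing.
* **Bellows-type density dependence.** Juveniles suffer extra per-capita
  mortality (αJ)^{β−1} with J the total juvenile density across genotypes.
  β > 1 is required; larger β means faster rebound after perturbation. The
  printed units of α are treated as a numeric scale (its dimensions are not
  self-consistent for non-integer β); only the product αJ matters.
* **Constant-rate continuous releases.** Releases add adults at total rate
  r·M̄/7 per day (r = weekly ratio to the equilibrium male density M̄),
  held constant regardless of how the population responds. Combination
  strategies switch strain at T_s; all comparisons are equal-effort (same
  total released for every sex composition). Female allocations of the
  KKaa (FK) strain are reassigned to males, because FK females are
  competent vectors; kkAA and KKAA females carry A and are released as
  specified.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| μ_J  | juvenile background mortality | 0.03 | day⁻¹ |
| μ_F  | adult female mortality | 0.10 | day⁻¹ |
| μ_M  | adult male mortality | 0.28 | day⁻¹ |
| λ    | larval production per female | 8 | day⁻¹ |
| ν    | emergence rate | 0.14 | day⁻¹ |
| α    | density-dependence scale | 2×10⁻⁴ | (αJ dimensionless) |
| β    | density-dependence strength | 3.4 | — |
| c_K, c_A | homozygous fitness costs | 0 | — |
| r    | weekly release ratio | 1 | × M̄ week⁻¹ |
| T    | release duration | 100 | days |
| T_s  | combination switch time | 50 | days |

The defaults are the standard *Ae. aegypti* field parameterization this
model family uses; they give a wild-type equilibrium J* ≈ 1.01×10⁴,
F̄ ≈ 7.08×10³, M̄ ≈ 2.53×10³ per habitat unit, computed in closed form
(J* = (1/α)(λν/(2μ_F) − ν − μ_J)^{1/(β−1)}, F̄ = νJ*/2μ_F, M̄ = νJ*/2μ_M)
and verified against a numerical steady-state root.

## Efficacy metrics

All metrics are functionals of the relative competent-vector density
F₉(t)/F̄ (wild-type adult females, the only viable females with no A
allele):

* **minimum** — the transient trough over the run;
* **long_term** — the endpoint of a run extended well past the end of
  releases. "Long term" is operationalized as a converged post-release
  steady state: the default horizon is 3 years past the last release, the
  endpoint is accepted when the relative change over the final 30 days is
  below 10⁻⁵ (values below 10⁻¹⁰ count as elimination), and the ranking
  and crossover helpers double the horizon (cap 15 years) until converged;
* **rel_avg** — the time average of F₉/F̄ over [t₀, t_f], default from
  release start to one year after the last release (t_f = 465 d for
  T = 100), by composite trapezoidal quadrature on the dense output grid.

## Maintenance releases

When the AP gene carries a fitness cost, any reduction is temporary unless
releases continue. The maintenance protocol runs the original-ratio
releases until the relative competent density first falls to a threshold
θ (detected by root-finding on the integrated trajectory), then switches
to releases at fraction r_p of the original ratio for a 730-day horizon.
*Recovery* is defined as the relative competent density exceeding its
trigger-time level at any time in the horizon (a configurable choice; the
paper-style "prevent a recovery" wording admits stricter readings, and the
recovery predicate is exposed separately from the minimizer). The minimal
r_p is found by bisection on a 0.01 grid, using the monotonicity of
recovery in r_p.

θ is a free protocol parameter. For cross-strategy comparisons the package
derives it from the model: FK-only releases at the original ratio can hold
the competent density no lower than their sustained-release plateau
(≈ 0.26 of baseline at default parameters), so 1.01 × that plateau is the
only common trigger density all three single-strain programmes can reach.
This choice also makes the FK result exact: any r_p < 1 lets the density
re-equilibrate above the trigger level, so FK maintenance requires the full
original ratio.

## Numerical choices

* Stiff-capable adaptive integration (LSODA) with rtol 10⁻⁸, atol 10⁻¹⁰,
  split at every forcing discontinuity (release start, strain switch,
  release end, maintenance trigger) so the solver never steps across a
  jump; output on a 0.5-day grid.
* Negative excursions below 10⁻⁶ in density units (solver interpolation
  noise on states of order 10³–10⁴) are clipped to zero after each
  segment; anything larger raises an integration error. The right-hand
  side also clamps its input at zero so birth terms never see negative
  densities.
* Crossover searches bisect the deterministic metric difference to 10⁻³
  in the parameter; an interval without a sign change is reported as
  "no crossover", not an error.
* The maintenance trigger uses the solver's event detection (downward
  crossing of θ), with a hard cap of 3000 days on the initial phase.

## Stochastic analog

The continuous-time Markov chain mirrors the deterministic system
term-by-term on integer counts: births per genotype at rate B_i, juvenile
deaths at (μ_J + (αJ)^{β−1})J_i, emergence at νJ_i with a fair-coin sex
draw and Bernoulli(γ_i) female survival, adult deaths at μ_F F_i and
μ_M M_i, and releases as Poisson arrivals at the deterministic forcing
rates (a batch-release mode is deliberately omitted to keep the process a
time-homogeneous CTMC within each forcing segment). Two integrators are
provided: exact Gillespie simulation (default; practical for reduced
population scales, obtained by rescaling α) and fixed-step tau-leaping
(step ≤ 0.01 d) vectorized across replicates for equilibrium-scale runs.
Replicates are seeded via spawned seed sequences, so results are exactly
reproducible given a seed. The rate catalogue is tested to sum to the L1
norm of the deterministic flux decomposition at the same state, and
replicate means are tested against the ODE trajectory at two population
scales.

This construction is the canonical event-per-term analog of the
deterministic model, built here as a faithful reconstruction; comparisons
between the two model types in this package are therefore internal
consistency checks, and the tau-leap integrator carries the usual O(τ)
bias (kept below Monte-Carlo error at the tested scales).

## What the simulator does and does not emulate

The scenarios are entirely self-generated: the model is initialized at the
wild-type demographic equilibrium and perturbed only by releases, which is
the idealized setting the strategy comparisons assume. Passing tests
therefore demonstrate internal correctness of the inheritance,
demographic and release machinery and reproducibility of the comparative
conclusions under these idealizations — not their robustness to features
of real populations that the model omits: spatial structure and local
extinction–recolonization, seasonality, age/size structure within stages,
mating competitiveness differences of released males, linkage
disequilibrium beyond what two unlinked loci generate, and genetic drift
at low density (the deterministic model is known to be optimistic about
elimination; the CTMC analog restores demographic noise but not space).

## Known limitations

* Release rates do not track the declining population (constant-rate
  policy), and pulsed batch releases are not modeled.
* Fitness costs act only on egg-to-larva survival; cost modes acting on
  mating success or adult longevity are out of scope.
* The maintenance trigger compares only the competent class F₉; protocols
  triggered on total population size would need a different event
  function.
* `long_term` for scenarios with very slow transgene turnover (small
  positive c_A) converges slowly; the convergence check extends the
  horizon but values near the cap carry a warning flag.
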
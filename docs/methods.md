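# Methods

## The measurement problem

A timed infusion of `13C`-labeled acetate into the coronary circulation
labels the TCA-cycle intermediates of the perfused myocardium; metabolism
is arrested before isotopic steady state (the pre-steady-state snapshot) and
the `13C` NMR multiplets of glutamate are quantified in small tissue
extracts.  Because glutamate exchanges with alpha-ketoglutarate, its
labeling pattern at a single, known time encodes the TCA-cycle flux and the
fraction of acetyl-CoA derived from the labeled substrate.  The package
estimates five parameters per tissue sample:

| parameter | meaning | units | role |
|---|---|---|---|
| `j_tca` | TCA cycle flux | umol min^-1 gdw^-1 | primary |
| `p_dil` | unlabeled (endogenous) fraction of acetyl-CoA | - | primary |
| `j_exch` | transamination exchange flux (alpha-KG/glutamate, OAA/aspartate) | umol min^-1 gdw^-1 | auxiliary |
| `t_trans` | acetate-to-acetyl-CoA transport/conversion time constant | min | auxiliary |
| `p_anap` | anaplerotic inflow relative to `j_tca` | - | auxiliary |

`gdw` = grams of tissue dry weight.

## Carbon-transition model

The network (`lipsss.network.default_config`) contains ten pools: three
forcings (infused acetate, the unlabeled dilution pool, the anaplerotic
source) and seven dynamic pools - acetyl-CoA (2 carbons), citrate (6,
lumping cis-aconitate and isocitrate), alpha-ketoglutarate (5), succinate
(4, lumping succinyl-CoA), oxaloacetate (4, lumping malate and fumarate),
glutamate (5) and aspartate (4).  Each dynamic pool with *n* carbons
carries `2^n` isotopomer-fraction state variables (bit *i-1* = carbon *i*),
180 states in total for the default network.

Atom maps: citrate C1-C4 derive from oxaloacetate C1-C4 and citrate C5/C6
from the acetyl carboxyl/methyl carbons; on conversion to
alpha-ketoglutarate the OAA-derived C4 leaves as CO2, the methyl carbon
arrives at alpha-KG C4 and the carboxyl at C5 (so methyl-labeled acetate
labels glutamate C4 first, the canonical observation).  The
alpha-KG -> succinate step is a symmetric pair of weight-0.5 atom maps
(succinate scrambling); succinate -> OAA is an identity map.  Anaplerosis
enters as unlabeled succinate at rate `p_anap * j_tca`, balanced by an
equal efflux at OAA; the carry flux succinate -> OAA is
`j_tca * (1 + p_anap)` so every pool is at steady state.  Both
transamination exchanges share the single parameter `j_exch` with identity
atom maps.

Acetyl-CoA dynamics are folded into a mono-exponential relaxation of its
composition toward the schedule target `(1 - p_dil) * infused species +
p_dil * unlabeled` with time constant `t_trans`; the citrate-synthase draw
samples the current composition without depleting it (the replenishment is
part of the relaxation).  All other fluxes move isotopomers per their atom
maps, scaled by `flux / destination concentration`; because inflow equals
outflow for every pool, the per-pool fraction sums are conserved exactly.

Default concentrations (umol/gdw): acetyl-CoA 0.05, citrate 1.0, alpha-KG
0.5, succinate 0.5, OAA 0.1, glutamate 20 (overridden per sample by the
assayed pool size - results are sensitive to it), aspartate 5.  The small
intermediate pools are order-of-magnitude literature placeholders; they
equilibrate fast relative to glutamate and have little influence on the
simulated multiplets.  All are overridable in the YAML configuration.

The default infusion schedule is 4 min of [2-13C]acetate followed by
1.5 min of [1,2-13C]acetate; sampling at t = 5.5 min.

## Numerics

Two integration paths share one compiled system:

* **Reference** (`simulate`): LSODA with analytic Jacobian, rtol 1e-8,
  atol 1e-10, hard restart at the 4.0-min phase switch.  Used for
  reporting, trajectory output, and the synthetic-data generator.
* **Fitting loop** (`simulate_fast`): an adaptive explicit Cash-Karp RK5(4)
  on the sparse system, fully compiled, with the step capped at
  `2 / max turnover rate` (the balance system's spectrum is bounded by its
  fastest pool turnover).  It agrees with the reference path to ~1e-9 in
  the isotopomer fractions at default tolerances (rtol 1e-6, atol 1e-9)
  and costs a few milliseconds.  When a proposed parameter set is so
  extreme that the explicit method would need more than ~4000 stability-
  limited steps, the evaluation falls back to LSODA, so no region of
  parameter space stalls the samplers.

Fractions can undershoot zero by integrator tolerance (~1e-10); they are
not clipped, and conservation is asserted to 1e-6 in the tests.

## Cost function and priors

`C(theta) = 1/2 sum_i ((m_sim_i - m_exp_i)/sigma_i)^2 + sum_j prior_j`,
summed over all multiplets present in the sample - including zero-assigned
ones (below-detection multiplets recorded as 0 with their noise SD), which
carry real information.  The simulated multiplet intensities are sums of
isotopomer fractions; per observed carbon they partition the positional
enrichment.  The default catalog holds the eleven canonical glutamate
multiplets (C2: S/D12/D23/Q; C3: S/D/T with the two one-neighbor doublets
lumped, as their couplings are equal; C4: S/D34/D45/Q); datasets may use
any subset.

Priors (auxiliaries only):

* `t_trans ~ lognormal(ln 0.202 min, sigma 0.336)`.  The width follows the
  95%-interval factor rule `sigma = ln(f)/2` with `f = 1.96`.
* `j_exch / j_tca ~ lognormal(ln 1, sigma = ln(15)/2 = 1.3540)`, a very
  weak prior spanning the 0.07-15 range of literature ratios.  (Historical
  reports print this width as 1.345; the formula it is defined by gives
  1.35403..., which is what the package computes.  The 0.7% difference is
  far below the prior's own uncertainty.)
* `p_anap`: uniform on [0, 1] continued by a half-normal tail (sd 0.3)
  above 1, with constants `c2 = 1/(0.5 + 1/(sigma sqrt(2 pi)))`,
  `c1 = 1 - c2/2` making the density continuous and of unit integral.  The
  constant `-ln c1` on [0, 1] is kept in the reported cost (it cancels in
  MH ratios but keeps `C(theta)` reproducible).

No priors constrain the primary parameters `j_tca`, `p_dil`.  A global
`prior_scale` factor multiplies every prior SD (2.0 reproduces the
doubled-prior sensitivity analysis; each lognormal term falls exactly 4x).

## Estimation: grid, simplex, ensemble

1. **Grid scan**: exhaustive evaluation over a configurable grid (default
   7 log-spaced points per positive parameter spanning a factor 30 around
   physiologic midpoints, 5 linear points for `p_dil`); the cost basin is
   shallow and multimodal, so a global scan precedes any local step.  Ties
   break to the first grid index, keeping runs deterministic.
2. **Simplex**: Nelder-Mead from the best grid point, in the sampling
   coordinates, convergence at cost improvement < 1e-8 or 5000
   evaluations; the result is never worse than its start.
3. **Ensemble**: adaptive Metropolis-Hastings random walk sampling
   `Pr(theta|D) ~ e^{-C(theta)}` (default 35,000 kept draws after a 10%
   burn-in).

The sampling coordinates are `(ln j_tca, ln j_exch, ln t_trans,
logit p_dil, p_anap)`.  The log coordinates are the model's natural
parameters - the auxiliary priors are Gaussian over the logarithms (their
omitted normalization is the log-space Gaussian's constant) - so the
acceptance ratio is the plain `e^{-C}` ratio with no Jacobian factor, and
the data-free marginal of `t_trans` is exactly
lognormal(ln 0.202, 0.336).  `p_anap` stays on the raw axis because its
prior is a normalized density over the ratio itself; negative proposals
are rejected.  Proposal scales adapt per 100-draw batch during burn-in
toward an acceptance fraction in [0.2, 0.5] with diminishing adaptation,
then freeze, so the kept chain is a fixed-kernel MH sample.  A generous
physiologic box (fluxes within 1e-4..1e4 umol/min/gdw) bounds the walk;
only samples whose data carry essentially no flux information reach it -
for them the `j_tca` direction has no proper posterior and the ensemble SD
correctly explodes.

For data-free (prior-recovery) runs the primary parameters must be held
fixed via `sample_mask`, precisely because their posterior is improper
without a data term.

Diagnostics: per-parameter integrated autocorrelation time (Geyer
initial-positive-sequence estimator; `inf` sentinel for a constant chain),
ensemble mean/SD/median and a histogram mode (Freedman-Diaconis bins -
the mode estimator is a package choice).  The reported point estimate for
the primary parameters is the **best fit**: the lowest cost seen anywhere,
optimization phases included.

**Quality criterion**: a sample is excluded iff the ensemble SD of
`j_tca` exceeds 10 umol/(min gdw) (the boundary value passes).  High
autocorrelation (default tau > 500 draws) in a primary parameter is
flagged for trace inspection but does not itself reject.

## Oxygen consumption

Per sample `MVO2 = (2 + p_dil) * j_tca`: full oxidation of one acetyl unit
consumes 2 O2, and the endogenous-substrate fraction adds one further O2
per turn on average.  (The formula is read as `(2 + p_dil) * j_tca`, not
`2 + p_dil*j_tca`: with the latter the estimate would be nearly
independent of the substrate mix, contradicting its stated derivation from
both primary parameters.)  Per heart, quality-passing samples are averaged
with dry-weight weights; the SEM over a heart's samples is unweighted (the
weighting convention for the error bar is not pinned down by the sources
this follows; unweighted is the simpler choice and is documented here).
`validate_against_gold` reports per-group and pooled Pearson correlations
against externally supplied gold-standard MVO2 values.

## Synthetic data and the stochastic oracle

`generate_sample` implements the validation measurement model: simulate
multiplets at known fluxes, add Gaussian noise with
`sigma = max(cv * intensity, floor)` (defaults cv 5%, floor 0.003 in
isotopomer-fraction units - fixture choices, not measured spectrometer
properties), and zero-assign measured intensities below a detection
threshold (default 0), keeping their SD.  `generate_cohort` draws a
multi-group cohort (defaults emulate a control/stenosis/inotropic-stress
design with group sizes 7/7/6/6/4/8 hearts and 9 samples per heart; the
group flux levels are fixture values).  Between-heart and within-heart
parameter spread is lognormal (CV 15% and 8%).  What the generator does
*not* emulate: spectral baseline/phasing artifacts, natural-abundance
background (assumed subtracted upstream), intensity-scale calibration
errors, or spatial correlation of flux within a heart - so passing
recovery tests demonstrate correctness of the estimation machinery, not
robustness to every property of real spectra.

`stochastic_oracle` is an independent check on the ODE compiler: a
discrete population of molecules advances by exponential-clock events
(rate `flux * N_target / C_target`); each event maps a uniformly sampled
source molecule through the transition's atom table and overwrites a
uniformly chosen molecule of the target pool, keeping pool sizes fixed.
For a flux-balanced network the expected occupancies obey exactly the
fraction-space balance equations, for any pool-size allocation.  The
allocation therefore only shapes the Monte Carlo error: upstream pools get
equal molecule shares and the observed pool a quarter share, so that the
observed pool's enrichment error is dominated by its own binomial noise
rather than by shared-ancestor correlations through the small
fast-turnover pools, and the quoted binomial standard errors are valid.

## Problem sizes used in the shipped studies

The package's own validation runs scale the studies to a single CPU: the
recovery study uses 20 replicates at 5,000 kept draws (the full protocol
keeps 35,000), the acceptance script 8 replicates at 2,000 draws plus a
24-sample cohort, and coarse 400-point grids stand in for the 12,000-point
production default.  These sizes give stable medians and correlations;
production analyses should use the defaults.

## Known limitations

* The atom-map network is the canonical cardiac acetate model; alternate
  anaplerosis plumbing (entry at OAA/malate, pyruvate cycling) is
  configuration, not code, but no alternate configuration ships.
* Natural `13C` abundance is assumed removed during spectral quantification;
  the initial condition is the pure unlabeled isotopomer.
* Intensities must arrive in absolute isotopomer-fraction units; raw
  spectrometer-unit scaling is upstream of this package.
* Single-chain diagnostics only (autocorrelation time); no multi-chain
  convergence statistics.
* The ensemble quantifies uncertainty given the model; structural error in
  pool lumping or concentrations is not propagated.
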
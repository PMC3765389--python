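# lipsss

Estimation of TCA-cycle fluxes and myocardial oxygen consumption from
single-time-point `13C` NMR measurements of glutamate in small tissue
samples (the LIPSSS protocol: *Labelling with Isotope for a
Pre-Steady-State Snapshot*), with full MCMC uncertainty quantification.

Intended users: groups running timed stable-isotope infusion experiments
in perfused tissue (here: acetate in myocardium) who quantify glutamate
`13C` multiplets per biopsy and need per-sample flux estimates with
honest confidence regions despite noisy spectra.

## The method in brief

An isotopomer balance model of the TCA cycle (ten metabolite pools, the
dynamic ones expanded into all `2^n` labeling states, 180 ODEs for the
default network) simulates the propagation of label from a timed
[2-13C]/[1,2-13C] acetate infusion into the glutamate pool.  Simulated
multiplet intensities m_sim(θ) depend on five parameters
θ = (J_TCA, J_exch, T_trans, P_dil, P_anap) and are matched to the
measured intensities through

    C(θ) = ½ Σ_i ((m_sim,i − m_exp,i)/σ_i)² + Σ_j prior(θ_j)

with weak lognormal priors on the auxiliary parameters (T_trans, the
ratio J_exch/J_TCA) and a uniform + half-normal prior on P_anap.
Estimation is three-phase: a global grid scan, Nelder–Mead simplex
refinement, and an adaptive Metropolis–Hastings random walk sampling the
posterior Pr(θ|D) ∝ e^(−C(θ)) (35,000 kept draws by default).  Samples
whose ensemble SD of J_TCA exceeds 10 µmol/(min·gdw) are excluded as
uninformative.  Oxygen consumption follows from the primary parameters as
MVO₂ = (2 + P_dil)·J_TCA per sample and as the dry-weight-weighted mean
per heart.  See `docs/methods.md` for the model, priors and numerics.

## Worked example

Simulate the labeling state of glutamate 5.5 min after the start of a
labeled infusion, at control-like fluxes:

```sh
$ lipsss simulate --j-tca 7 --j-exch 7 --t-trans 0.202 --p-dil 0.3 --p-anap 0.1
positional enrichments (C1..C5):
  C1: 0.048052
  C2: 0.140790
  C3: 0.140790
  C4: 0.412361
  C5: 0.123356
multiplet intensities:
  C2S: 0.081916
  C2D12: 0.013703
  C2D23: 0.033717
  C2Q: 0.011454
  C3S: 0.028869
  C3D: 0.080314
  C3T: 0.031608
  C4S: 0.229222
  C4D34: 0.059783
  C4D45: 0.084782
  C4Q: 0.038575
```

Glutamate C4 is the most enriched position (0.41): it receives the methyl
carbon of [2-13C]acetate on the first turn of the cycle, so its large C4
singlet is the leading flux signal at this early time point.  C2 and C3
(0.14 each) are labeled only on later turns — their rise relative to C4
is what encodes J_TCA.  C5 (0.12) comes from the carboxyl carbon, fed
almost exclusively by the final 1.5 min of [1,2-13C]acetate, and therefore
reports on the fast acetyl-CoA dynamics (T_trans).  Each carbon's
multiplets sum to its positional enrichment (e.g. C4: 0.2292 + 0.0598 +
0.0848 + 0.0386 = 0.4124).

A full synthetic round trip — generate a cohort with known fluxes, fit
every sample, aggregate per heart:

```sh
lipsss synth --out cohort.tsv --seed 11 --hearts 2 --samples-per-heart 3
lipsss run cohort.tsv --n-draws 5000 --grid-points 4 --seed 1 --out-dir results/
```

`results/sample_summary.tsv` then holds, per sample, the best-fit
parameters, ensemble mean/SD/median/mode, autocorrelation times and the
quality flag; `results/heart_summary.tsv` the per-heart MVO₂ with SEM;
`results/manifest.json` the seeds and configuration hash needed to
reproduce the run byte for byte.

## Layout

| module | contents |
|---|---|
| `lipsss.network` | pools, atom transitions, infusion schedule, YAML config |
| `lipsss.model` | isotopomer ODE compiler and integrators |
| `lipsss.nmr` | multiplet catalog, m_sim, sample records |
| `lipsss.inference` | cost function, priors, grid + simplex optimization |
| `lipsss.mcmc` | adaptive MH sampler, diagnostics, quality filter |
| `lipsss.physiology` | MVO₂ per sample/heart, gold-standard validation |
| `lipsss.synthetic` | synthetic cohorts, noise model, stochastic oracle |
| `lipsss.io`, `lipsss.pipeline`, `lipsss.cli` | tables, orchestration, CLI |
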
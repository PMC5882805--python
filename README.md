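# dilfret

Quantitative models for studying how large, dynamic oligomers of islet
amyloid polypeptide (IAPP, amylin) porate cell-derived membranes.  IAPP
aggregation is linked to β-cell loss in type 2 diabetes; on giant plasma
membrane vesicles (GPMVs) it produces two kinetically distinct leakage
phases, mediated by membrane-bound oligomers large enough that conventional
intramolecular FRET cannot characterise them.  `dilfret` implements the
analysis stack such experiments require:

- **Diluted-FRET Monte Carlo** — intermolecular FRET between donor- and
  acceptor-labelled monomers heavily diluted with unlabelled peptide
  (doping d:a:X, e.g. 1:1:500), simulated for isotropic spherical oligomers
  of *N* monomers at fixed protein density.  Only assemblies with *N* of
  order *X* are likely to carry both a donor and an acceptor, which makes
  the signal selective for large oligomers.
- **FCS autocorrelation fitting** — the single-species 3-D Brownian
  diffusion model with the structure factor fixed at the instrument-calibrated
  value, plus burst-count statistics for traces dominated by large species.
- **Two-phase leakage kinetics** — a piecewise
  exponential–plateau–exponential model with a lag, fitted by profiled
  nonlinear least squares, and BIC-based selection against a single-phase
  alternative.
- **Pixel FRET** — three-cube sensitized-emission efficiency maps with
  bleed-through calibration, ring-ROI histograms, and Gaussian-mixture peak
  decomposition under the exact binned likelihood.
- **Assay statistics** — percent toxicity from plate controls and the
  detected-acceptor fraction.
- **Synthetic-data generators** — forward models with known ground truth
  for every input the pipeline consumes, so the whole stack is testable
  without microscopy data.

## Core models

Pairwise Förster transfer efficiency at donor–acceptor distance *r* with
Förster distance *R*₀ (52 Å for the Alexa 488/Atto 647 pair):

    E(r) = R0^6 / (R0^6 + r^6)

A donor facing several acceptors treats each pair as an independent
transfer opportunity, so the combined efficiency is

    E = 1 − Π_j (1 − E(r_j))

(three acceptors at *R*₀ give 1 − 0.5³ = 0.875).  A simulated oligomer of
*N* monomers occupies a sphere of radius (3·N·v/4π)^⅓ at v = 4000 Å³ per
monomer; each monomer is independently donor/acceptor/unlabelled with the
doping-ratio probabilities, labelled monomers are placed uniformly in the
sphere, and trials are averaged (donor-free trials excluded, acceptor-free
donor trials scored 0) until the running mean converges.

FCS autocorrelation of one diffusing species (occupancy *N*, diffusion time
τ_d, structure factor *s* = 0.1 fixed):

    G(τ) = (1/N) · (1 + τ/τ_d)^−1 · (1 + τ/(s²τ_d))^−1/2

Two-phase leakage of normalised lumen intensity:

    I(t) = 1 − A1·(1 − e^{−k1 t})                      t ≤ T_lag
    I(t) = B + (I(T_lag) − B)·e^{−k2 (t − T_lag)}      t > T_lag

Pixel FRET from three channels with bleed-through coefficients β_d, β_a and
sensitized-emission scaling γ:

    F_c = I_fret − β_d·I_donor − β_a·I_acceptor,   E = F_c / (F_c + γ·I_donor)

Percent toxicity from sample ⟨S⟩, negative ⟨N⟩ and positive ⟨P⟩ controls:

    %toxicity = 100 − 100·(⟨S⟩ − ⟨P⟩)/(⟨N⟩ − ⟨P⟩)

## Worked example

```python
import dilfret as df

control = df.ConvergenceControl(min_trials=20_000, max_trials=20_000, seed=42)
curve = df.fret_vs_N_curve([10, 100, 500, 2000], ["1:1:100", "1:1:500"],
                           control=control)
print(curve.to_string(index=False))
```

```
  ratio    N  mean_fret  std_err  n_trials  n_donor_trials  converged
1:1:100   10   0.082004 0.006209     20000            1915      False
1:1:100  100   0.443815 0.003652     20000           12493      False
1:1:100  500   0.657002 0.001666     20000           19840      False
1:1:100 2000   0.759132 0.000733     20000           20000      False
1:1:500   10   0.022028 0.007261     20000             405      False
1:1:500  100   0.111640 0.004560     20000            3569      False
1:1:500  500   0.200898 0.002578     20000           12491      False
1:1:500 2000   0.258354 0.001483     20000           19597      False
```

The average efficiency rises with oligomer size toward a density-limited
plateau, and dilution (1:1:500 vs 1:1:100) suppresses it everywhere: at the
experimental 1:1:500 doping the simulated efficiency stays near ~0.26 even
for 2000-mers, so any observed pixel efficiency well above that ceiling
cannot come from an isotropic, density-packed sphere.  (`converged=False`
here only records that the fixed 20 000-trial budget ended the run rather
than the running-mean criterion.)

Fitting a synthetic two-phase leakage trace at 2% noise recovers the
generating kinetics:

```python
trace = df.make_leakage_trace(noise_sd=0.02, seed=0)
fit = df.fit_two_phase(trace)
sel = df.select_phase_model(trace)
```

prints parameters `k1=0.0337  A1=0.479  T_lag=1400  k2=0.0454  B=0.000`
(truth: 0.033, 0.48, 1400 s, 0.049, 0) and selects `two_phase`
(BIC −15601 vs −7802 for the single-phase alternative).

A command-line interface mirrors the library:
`dilfret simulate-fret`, `fit-fcs`, `burst-stats`, `fit-leakage`,
`pixel-fret`, `toxicity`, and `dilfret synth {leakage,fcs,scene,histogram}`
for generating matching synthetic inputs; all subcommands take explicit
seeds and write provenance headers.

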
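# Methods

This note documents the models implemented in `dilfret`, the assumptions
and numerical choices behind them, and what the synthetic-data generators
do and do not emulate.

## Diluted-FRET Monte Carlo

**Model.** An oligomer of *N* monomers is an isotropic sphere of volume
*N·v* with *v* = 4000 Å³ per monomer (protein-like density), so the radius
grows as *N*^⅓.  At doping d:a:X each monomer is independently
donor-labelled with probability d/(d+a+X), acceptor-labelled with
a/(d+a+X), unlabelled otherwise — a per-monomer trinomial rather than an
exact multinomial partition, matching the binomial description of labelling
stoichiometry and avoiding small-*N* edge cases.  Labelled monomers are
placed uniformly at random in the sphere each trial.  A donor facing
acceptors at distances *r_j* transfers with probability
1 − Π(1 − E(r_j)), the independent-probability combination rule; this rule
(not kinetic rate competition, which would give 0.75) reproduces the
three-acceptors-at-R₀ value of 0.875.  Multi-donor trials score the
unweighted mean over donors — the per-donor-photon expectation; no
aggregation rule is forced by the physics, and at experimental dilutions
multi-label trials are rare enough that the choice is immaterial (the
nearest-acceptor approximation differs from the full rule by < 0.02 at
1:1:500, asserted in the tests).  Donor–donor and acceptor–acceptor
couplings, orientation-factor variation, excluded volume, linker geometry
and photophysics are all outside the model.

**Averaging convention.** Trials with no donor emit no FRET-channel signal
and are excluded from the average; donor-bearing trials with no acceptor
count as efficiency 0.  Under this convention the mean efficiency rises
from ~0 for small oligomers to a density-limited plateau, and at 1:1:500
with R₀ = 52 Å the sweep over N = 2–5000 stays below ≈ 0.29 (a
semi-analytic Poisson-acceptor edge-effect integral gives the same
0.20 → 0.28 progression over N = 500 → 5000, so the ceiling is a property
of acceptor number density, not of the trial budget).

**Dynamics.** Fluorophore positions are redrawn independently every trial.
This represents the rapidly-equilibrating regime — narrow observed
efficiency distributions implying averaging over conformations faster than
the acquisition — by averaging over placements instead of simulating
diffusion inside the oligomer.

**Convergence.** The running mean over donor-bearing trials stops when it
changes by less than 10⁻³ across a 1000-trial window, with at least 10⁴ and
at most 10⁶ trials; a run that exhausts the budget is flagged
`converged=False` rather than raised, since the partial mean and its
standard error remain valid Monte-Carlo estimates.  Fixed-budget runs
(min = max) therefore always carry the flag.  With a fixed seed results are
bit-reproducible; grid runs derive one child seed per (ratio, N) cell.

## FCS

The single-species 3-D Brownian autocorrelation
G(τ) = (1/N)(1+τ/τ_d)⁻¹(1+τ/(s²τ_d))^{-½} is fitted by unweighted least
squares with the structure factor fixed (default 0.1, the free-dye
calibration convention); N is initialised from the zero-lag amplitude and
τ_d from the half-decay lag.  The diffusion coefficient D = w²/(4τ_d)
requires the lateral beam waist, an instrument calibration the analysis
cannot infer; it is a config parameter (default 0.25 µm) echoed into every
report, and reported D values are meaningful only relative to it.

Traces dominated by large, slow species are summarised by burst counts:
maximal runs of bins above background + 5 SD.  The background level is the
median count and its SD the scaled median absolute deviation floored by the
shot-noise SD √(median); a lowest-quartile estimator was rejected because
for integer Poisson-like counts the lowest quartile is identically zero,
producing a degenerate threshold.

## Leakage kinetics

The two-phase-with-lag curve is the minimal parametric form with an
exponential first phase to a plateau at 1−A1, a lag, and a second
exponential to a floor B (B > 0 accommodates variants whose second phase
does not reach baseline); continuity at the lag is built into the
parameterisation.  Rates are expressed per unit of the trace's own time
axis and never hard-coded.  The generator's default kinetics are
A1 = 0.48, T_lag = 1400 s, B = 0, with k1 = 0.033 s⁻¹ and k2 = 0.049 s⁻¹:
rate constants of tens of s⁻¹ would be dimensionally inconsistent with a
1400 s lag on the same axis (a first phase over in ~0.1 s cannot plateau
over minutes), so the generator carries the rate magnitudes at 10⁻³ of
those printed values, giving a ~30 s first-phase time constant consistent
with minute-scale kinetics.

**Fitting.** T_lag is the awkward parameter — a piecewise switch with a
weak gradient — so it is profiled first: for 19 candidate lags the
remaining parameters come from cheap log-linear regressions on the two
segments (plateau from a local median; rate regressions stop at the first
point reaching baseline so late noise outliers cannot flatten the slope),
and the lowest-RSS candidate seeds the released five-parameter fit,
alongside a knee-heuristic start.  A converged parameter vector whose
error-bar estimation failed is still accepted on its residual.  Fits whose
lag runs into the end of the trace or whose second-phase amplitude is below
max(3·residual SD, 0.01) are flagged `boundary_degenerate` (second phase
unidentifiable) instead of raised.  At 1–2% additive noise the fitter
recovers all five generating parameters with < 0.5% bias over 100
replicates.

**Model selection** between single-phase (exponential to plateau) and
two-phase is by BIC; an F-test is inappropriate because the lag parameter
sits on the boundary of the nested model.  A degenerate two-phase fit never
wins.  On pure noise the false-two-phase rate is below 5%.

## Pixel FRET

Standard three-cube sensitized emission: F_c = I_fret − β_d·I_donor −
β_a·I_acceptor and E = F_c/(F_c + γ·I_donor), with γ a calibration input
(default 1).  β coefficients come from Theil–Sen regression of the FRET
channel on the source channel over single-label calibration images,
restricted to pixels above a quarter of the robust (99.9th-percentile) peak
brightness — dim pixels near the background threshold are shot-noise
dominated and drag a median-of-pairwise-slopes toward zero.  Each channel
has its background level (mean of its dimmest half) subtracted before
correction, since camera offset in the FRET channel otherwise masquerades
as sensitized emission; negative corrected-FRET pixels are clipped to 0 and
retained (exclusion available by flag).  The default validity mask keeps
donor pixels above mean + 2 SD of the dimmest half of the donor channel.
For peak statistics on puncta a stricter mask (e.g. acceptor channel above
a quarter of peak, which is efficiency-independent) is recommended and used
in the end-to-end tests, because low-count pixels carry high-variance
efficiency estimates that blur mixture components.

**Peak decomposition.** Efficiency histograms are decomposed into Gaussian
mixtures fitted directly to the binned counts under the exact binned
likelihood — component bin probabilities are Gaussian CDF differences, and
the M-step uses truncated-normal conditional moments within bins.  The
second-moment (smearing) approximation was rejected because it lets narrow
components gain spurious likelihood by tiling wide bins.  EM is
deterministic (quantile-seeded, tolerance 10⁻¹⁰); the component count is
chosen by BIC with n equal to the total histogram count, so a
100 000-pixel histogram resolves four overlapping components while a
200-pixel ROI histogram is not over-fitted.  Fitted parameters are exactly
invariant to rescaling all counts by a constant; the BIC-chosen component
count is invariant in all tested cases, though in principle count scale is
statistical information and may move a marginal choice.  Known limitation:
a broad component nested under a narrow one (0.41 ± 0.08 beneath
0.36 ± 0.04) is weakly identified, and its maximum-likelihood position
wanders by about ±0.03 between 10⁵-sample realizations — this is
estimation error, not an optimizer artifact (EM initialised at the truth
converges to the same deviated solution).  Recovery claims are therefore
stated for positions averaged over replicate realizations.  A genuinely
uniform density is approximated by several broad components (it is outside
the Gaussian family), with narrow components appearing only at the sharp
support edges; the dispersion score, a weighted SD including the
within-bin width²/12 term, is the robust broad-vs-narrow discriminator.

## Synthetic data

Generators are pure functions of (parameters, seed) and their defaults are
the studied conditions: leakage traces at the kinetics above (2 s sampling,
4000 s duration, 1% additive Gaussian noise); autocorrelation curves
averaged over 30 repeat sweeps with 1% multiplicative noise per sweep;
imaging fields of 192×192 px with a faint vesicle rim of radius 60 px and
two membrane puncta at efficiencies 0.36 and 0.62 (donor amplitude 800,
acceptor 600 expected counts, bleed-through 0.2/0.1, γ = 1); mixture
histograms at the observed peak sets, truncated to [0, 1] by rejection so
no artificial point mass accumulates at the boundaries.  Noise defaults are
generic confocal statistics: Poisson shot noise on expected counts plus
Gaussian read noise of SD 2 counts, and a uniform baseline of 3 counts.

What passing tests show: every estimator recovers its own forward model's
parameters at realistic noise, the pipeline's stages compose, and the
Monte-Carlo simulator agrees with closed-form and enumeration oracles.
What they do not show: performance on real microscopy, where the point
spread function, z-sectioning, membrane undulations, photobleaching,
autofluorescence and detector nonlinearity are all absent from the
generators; the published experimental fit values are used here only as
generator ground truth, not as quantities this package can re-derive from
raw data.

## Problem sizes

Default analysis and test scales: 2×10⁴ Monte-Carlo trials per (ratio, N)
cell for simulation sweeps; 100 replicate fits for leakage recovery, 50 for
FCS; 10⁵ samples per mixture histogram with positions averaged over 5
realizations; 5 rendered scenes for pixel-FRET recovery.  These sizes give
Monte-Carlo standard errors comfortably below the effect sizes being
checked while keeping a full run of the suite and the acceptance script in
the minutes range on one CPU.
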
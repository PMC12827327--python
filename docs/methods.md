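# Methods

Models, estimators and numerical choices in `actokin`, with the
reasoning behind the defaults.  Units are µM and seconds throughout;
filament lengths in µm, velocities in nm/s, sedimentation coefficients
in Svedberg (1 S = 1e-13 s).

## Nucleation–elongation model

Bulk assembly is modelled as mass-action nucleation plus elongation at
a single effective (barbed) end class:

    dN/dt = k_nuc_eff · G^n_c
    dP/dt = N·(k_on·G − k_off) + n_c·k_nuc_eff·G^n_c,   G = A − P

where N is the filament-end concentration, P polymerized actin, G free
monomer, A total actin, and n_c = 3 (a trimeric nucleus — the smallest
species that elongates rather than dissociates).  Each new nucleus
deposits its n_c subunits into P, so mass is conserved exactly.  The
reported signal is the polymer mass fraction F_norm = P/(A − Cc)
clipped to [0, 1], matching a pyrene readout normalized between its
baseline and plateau; Gaussian noise is added to the signal only and
the noiseless state is kept as ground truth.

Defaults: k_on = 10.3 µM⁻¹s⁻¹ and k_off = 1.4 s⁻¹ for the barbed end
(Cc ≈ 0.136 µM), k_on = 1.3 µM⁻¹s⁻¹ and k_off = 0.8 s⁻¹ for the
pointed end (textbook values; the pointed-end Cc ≈ 0.6 µM).
k_nuc_base defaults to 2e-6 µM⁻²s⁻¹, chosen so that 2 µM actin
completes assembly in tens of minutes with peak end concentrations of
~1–2 nM — the regime of plate-reader pyrene assays.

Nucleation enhancement by a capper is a linear multiplier,
k_nuc_eff = k_nuc_base·(1 + e·[capper]).  This is a deliberately
phenomenological stand-in: thioredoxin-fold cappers stimulate
nucleation, presumably by stabilizing dimers/trimers, but no
mechanistic rate law is established, so the simulator exposes a single
interpretable slope instead of pretending to structural detail.

The integrator is LSODA (stiff-safe, adaptive) at rtol 1e-8/atol
1e-12.  G is floored at 0 inside the rate law to keep the power G^n_c
defined under tiny negative excursions.

### Stochastic counterpart

`gillespie_assembly` runs the exact SSA over {nucleation (n_c monomers
→ one filament), +1 subunit per end, −1 subunit per end} with 64-bit
counters; concentrations map to counts through Ω = V·N_A (≈ 602
molecules per µM·fL).  Mass conservation is asserted at every event.
The nucleation propensity uses the macroscopic form k_nuc·(g/Ω)^n_c·Ω;
at the copy numbers used for validation the O(1/g) difference from the
falling-factorial form is far below sampling noise.

A caveat that shaped the validation suite: for the *nonlinear*
nucleation pathway the ODE is not the mean of the jump process — G³
fluctuations and the anticorrelation between nuclei and free monomer
give an O(1/Ω) gap, measurable once a few hundred SSA runs are
averaged.  Equivalence at Monte-Carlo precision (3 SE over 200 runs)
is therefore asserted on a seeded, nucleation-free small system (301
monomers, 10 ends), whose linear kinetics make the ODE the exact SSA
mean; the nucleation pathway is checked separately against a relative
bound (SSA mean within 5% of total actin of the ODE at ~600
molecules; measured ≈ 2.6%).

## Seeded pointed-end assays

Both seeded assays treat capper binding as rapid-equilibrium occupancy
θ = c/(K + c) — no capper on/off kinetics, appropriate when binding
equilibrates fast compared with the kinetic readout.

* Elongation from barbed-end-capped seeds:
  dP/dt = E·(k_on·G − k_off) with active ends
  E = seed_ends·(1 − block_fraction·θ); integrated in closed form.
  Default seeds 2 nM ends with 2 µM monomer.
* Dilution-induced depolymerization:
  F(t) = F_∞ + (F_0 − F_∞)·exp(−k_app·t) with
  k_app = k_dep0·(1 − protect_fraction·θ), k_dep0 = 0.01 s⁻¹.

`block_fraction` and `protect_fraction` separate the two capping
phenotypes observed for this protein class: full block of subunit
addition (block ≈ 1, nanomolar K) but only partial protection against
subunit loss (protect < 1, micromolar half-effect).  Depolymerization
titrations are generated with protect = 0.8 for the weak cappers and
0.95 for tropomodulin, reflecting the strong residual protection
difference between the two.

## Trace descriptors

* Normalization: F_norm = (F − F_min)/(F_plateau − F_min) with F_min
  and F_plateau the means of the first and last 5% of samples.  The
  5%-edge estimator is robust to edge noise but assumes the recording
  starts near baseline and ends on the plateau; a trace without net
  increase raises rather than returning a degenerate scale.  All
  descriptors are thereby invariant to affine rescaling of the raw
  signal.  Note the normalizer is the identity only for traces whose
  edge windows are genuinely flat: an autocatalytic onset is
  polynomial in t, so the first-5% mean of a simulated trace is small
  but nonzero.
* Bulk rate: least-squares slope over points with F_norm ∈
  [0.35, 0.65]; if fewer than 5 points fall in the band it widens
  symmetrically in 0.05 steps (deterministic on sparse traces).
* Lag time: first crossing of F_norm = 0.05, linearly interpolated.
* Mono-exponential fits: offset + A·exp(−k·t) by bounded
  Levenberg–Marquardt with log-linearized initial guesses and rate
  restarts; flat traces are flagged `degenerate` instead of reporting
  a spurious rate.
* Initial elongation rate: slope over the initial window in which the
  signal has risen ≤ 15% of its total amplitude, minimum 8 points.
  The window introduces a small downward bias (the rate decays across
  it); recording only the initial phase of the assay keeps the bias
  per trace ≈ 1% and largely cancels in control-normalized ratios.

### Filament-end inversion

    [ends] = (dF/dt·(A − Cc)) / (k_on·(A·(1 − F) + Cc·F) − k_off)

The derivative is a Savitzky–Golay filter, window 11 points, order 2
(configurable): wide enough to suppress noise amplification, short
enough to track the sigmoidal flux peak at typical plate-reader
sampling (≈ 5 s).  The equation degenerates to 0/0 as F → 1, so
points with F_norm > 0.95 or with the denominator below 1e-3 of its
F = 0 value are masked invalid; derivative noise can push isolated
estimates slightly negative, which are floored at 0.  On noiseless
simulations sampled at 5 s the inversion recovers ground-truth end
concentrations within 5% for 0.05 < F_norm < 0.90 (the error is
dominated by the polynomial-window bias in the high-curvature onset
and grows with coarser sampling).

## Titration fits

Rates are averaged per concentration, divided by the 0-concentration
control (first-order SD propagation includes the control's own
uncertainty), and fitted with

    y = y0 + (ymax − y0)·xⁿ/(Kⁿ + xⁿ),   y0 = 1, n = 1 fixed.

ymax is free in both modes (bounded to [0, max(y)]): elongation data
decide themselves whether the cap is complete, and depolymerization
protection is demonstrably partial.  Two estimator choices differ from
the obvious defaults, both after measurement:

* **Unweighted by default.** Inverse-variance weighting from
  triplicate SDs uses variance estimates with 2 degrees of freedom;
  on synthetic titrations (σ = 0.05) it doubled the bias of K̂ (6.4%
  vs 3.6% mean relative error).  `weighted=True` restores weighting
  for datasets with enough replicates.
* **Bootstrap SD.** `sd_k_half` is a nonparametric bootstrap over
  concentration points (default 1000 resamples, seeded).  On 100
  synthetic titrations the ±2·SD interval covers the truth ≈ 80% of
  the time — slightly anticonservative, as expected for a bootstrap
  over ~11 design points; treat it as a scale, not an exact CI.

Per-seed sampling error of K̂ under triplicates at σ = 0.05 is ~8–9%
(so single-titration estimates scatter up to ~25%); means over tens of
seeds are accurate to a few percent, with a small downward bias from
the ymax ≥ 0 boundary when the true residual activity is 0.

## TIRF field model and estimators

Nucleation events are Poisson with intensity k_nuc·area and uniform
birth times; each filament grows at a per-filament velocity drawn from
Normal(v_mean, v_sd) truncated at 0; observed lengths add Gaussian
noise (default 20 nm); a filament is counted from the first frame its
observed length reaches `detect_min_length` (0.5 µm) and stays counted
(sticky detection).  No disassembly, annealing, fragmentation or
photobleaching: the estimators analyze growth only.

The nucleation-rate estimator excludes the first 10% of frames
(detection onset), trims a trailing saturation plateau (tail growing
slower than 25% of the overall trend), and fits one least-squares
line.  A rolling local-linearity criterion was evaluated and rejected:
filament density is a counting staircase, and on realistic fields
(~20 filaments per 6400 µm² in 600 s) short windows routinely fail any
strict local R² threshold while the spans that pass are selected for
steepness, biasing k_nuc upward by tens of percent.  The global fit is
unbiased (mean error ≈ 1% over 50 seeds at the default operating
point); an overall R² below 0.5 raises, since such a course has no
single nucleation rate.  Detection lag (threshold/velocity ≈ 18 s)
shifts the line's intercept, not its slope.

Elongation rates are per-filament linear fits of length vs time
(≥ 5 frames, shorter tracks excluded and counted).  The subunit
conversion divides by a helical rise of 2.73 nm/subunit, the value
that reconciles 28.1 nm/s with ~10.3 subunits·s⁻¹ at 1 µM actin.

## Hydrodynamic arithmetic

Average-isotope residue masses (Biopython's tables) plus one water;
partial specific volume as the Cohn–Edsall mass-weighted average of
the standard residue v̄ table (consensus literature values, shipped in
`VBAR_RESIDUE_ML_G`); buffer correction
s20,w = s·(η_b/η_20,w)·(1 − v̄ρ_20,w)/(1 − v̄ρ_b) with water-at-20 °C
constants ρ = 0.99823 g/mL, η = 1.002 cP; frictional ratio
f/f0 = [M(1 − v̄ρ)/(N_A·s)] / [6πη·(3Mv̄/4πN_A)^{1/3}].  Buffer
density and viscosity are user inputs — no buffer-composition
calculator is included.  f/f0 < 1 warns but returns, keeping
inconsistent inputs visible.  For a 13 kg/mol protein at 1.55 S the
ratio is 1.31 at v̄ = 0.725, and anywhere in [1.23, 1.35] for v̄ in
[0.72, 0.74]: a composition-level v̄ uncertainty of ±0.01 moves f/f0
by ~±0.03.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the estimators rely
on — sigmoidal mass-fraction kinetics, hyperbolic occupancy, Poisson
appearance with linear growth, additive Gaussian measurement noise —
with seeded RNG everywhere, so recovery tests demonstrate estimator
correctness and calibration under those assumptions.  They do not
model photobleaching, baseline drift, ATP-hydrolysis/nucleotide state,
filament fragmentation or annealing, profilin competition, or
capper on/off kinetics; passing tests therefore validate the analysis
chain, not the absence of such effects in real data.  Problem sizes in
the test and acceptance runs (50 seeds, 50 filaments per field,
200 SSA runs, 400-point traces) were chosen as the smallest that hold
Monte-Carlo error comfortably below the tolerances being asserted.

## Degenerate inputs and tie-breaks

Flat traces: normalization and the hyperbolic fit raise
(`NoAssemblyError`, `UnresolvableFitError`); the mono-exponential fit
returns a flagged degenerate result.  Decaying traces under the
elongation reducer raise a degenerate-slope error annotated with the
capper concentration.  Sub-critical total actin (A ≤ Cc) is rejected
by the inversion.  Band widening for the bulk-rate window and the
≥ 5-point rule make sparse-trace results deterministic.  Seeds expand
through NumPy `SeedSequence.spawn`, so adding a pipeline stage never
perturbs the streams of earlier stages.
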
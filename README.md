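# actokin

Analysis of actin assembly kinetics from bulk and single-filament
assays, paired with a simulator that generates every assay type
synthetically so each analysis stage can be validated by parameter
recovery.

Actin polymerizes in two steps: an unfavourable nucleation step (a
trimeric nucleus) followed by fast, asymmetric elongation, with
association/dissociation rate constants k_on and k_off at each filament
end and a critical concentration Cc = k_off/k_on below which filaments
shrink.  Pointed-end capping proteins — tropomodulins and the
thioredoxin-fold capper family (TPEC/SH3BGRL) — bind the slow-growing
end, blocking subunit addition and (more weakly) subunit loss.
`actokin` is written for biochemists quantifying such regulators from
standard *in vitro* readouts.

## What it computes

* **Bulk pyrene traces** (`actokin.traces`): normalization to
  F_norm ∈ [0, 1], bulk polymerization rate (least-squares slope of the
  linear region around half-maximal signal), lag time (5% of final
  signal), mono-exponential rate constants, and the inversion of a
  normalized trace into a filament-end concentration time course:

      [ends](t) = (dF_norm/dt · ([actin]_total − k_off/k_on)) /
                  (k_on·([actin]_total·(1 − F_norm) + (k_off/k_on)·F_norm) − k_off)

  with dF_norm/dt from a Savitzky–Golay derivative.
* **Capping titrations** (`actokin.titration`): per-concentration rates
  normalized to the capper-free control and fitted with the hyperbolic
  isotherm y = y0 + (ymax − y0)·xⁿ/(K_Dⁿ + xⁿ) with y0 = 1, n = 1,
  giving the apparent K_D (inhibition of pointed-end elongation) or
  K_50% (protection against depolymerization), with a bootstrap SD.
* **TIRF filament fields** (`actokin.tirf`): filament-density time
  courses → apparent nucleation rate k_nuc (µm⁻² s⁻¹); per-filament
  length tracking → elongation rates (nm/s, convertible to subunits/s
  via the 2.73 nm helical rise).
* **AUC arithmetic** (`actokin.hydro`): composition-based molar mass
  and Cohn–Edsall partial specific volume, s → s20,w correction, and
  frictional ratios f/f0.
* **Simulators** (`actokin.model`, `actokin.tirf`): a deterministic
  nucleation–elongation ODE with a matched exact Gillespie simulation,
  seeded pointed-end elongation and dilution-depolymerization models
  with rapid-equilibrium capper occupancy, and Poisson filament fields
  — all seeded, all storing noiseless ground truth.

## Worked example

`examples/pointed_end_titration.py` simulates a seeded pointed-end
elongation titration (barbed ends capped, pointed-end capper with a
true K_D of 85 nM), reduces each trace to its initial elongation rate,
normalizes to the capper-free control and fits the isotherm:

```
true K_D    : 85.0 nM
fitted K_D  : 88.0 +/- 0.9 nM (bootstrap SD)
fitted ymax : 0.000  (residual activity at saturation)
```

The fitted K_D recovers the generating value within a few percent, and
ymax ≈ 0 reports a full cap (no residual elongation at saturation).
The other scripts in `examples/` cover the bulk assay with the
filament-end inversion, depolymerization protection (K_50%), TIRF
nucleation/elongation estimation, and the sedimentation arithmetic;
each prints the numbers it computes and a line on what they mean.

A thin CLI mirrors the library for shell use
(`actokin simulate-bulk`, `analyze-bulk`, `simulate-elongation`,
`simulate-depol`, `fit-titration`, `simulate-tirf`, `analyze-tirf`,
`hydro`); every stochastic run writes a JSON manifest with its seed.

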
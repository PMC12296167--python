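# bubston

Modelling toolkit for **ion-stabilized gas nanobubbles ("bubstons") in water**
and the weak GHz electromagnetic emission their oscillations can produce.

Milli-Q water open to the atmosphere carries a population of long-lived gas
nanobubbles. A bare gas bubble of radius *R<sub>b</sub>* ≲ 1 µm should
dissolve quickly: the Laplace pressure *P*₀ + 2Γ/*R<sub>b</sub>*
over-pressurizes the gas inside. The bubston model stabilizes the bubble
electrostatically: anions (chiefly HCO₃⁻) embedded in the bubble's boundary
layer carry a charge *Q*₀ whose outward ponderomotive (Maxwell-stress)
pressure *P<sub>e</sub>* = *Q*₀²/(8πε*R<sub>b</sub>*⁴) balances surface
tension, giving a stable radius

    R_b = [ Q0² / (16 π ε Γ) ]^(1/3)

The package implements, in CGS-Gaussian units throughout:

* **double_layer** — Debye–Hückel screening cloud around the charged shell
  (Bjerrum/Debye lengths, potential and charge-density profiles, exact
  diffuse-layer neutrality), ζ-potential ↔ charge conversion
  ζ = *Q<sub>c</sub>*/(ε*a<sub>c</sub>*) at the slipping surface, Stern-layer
  and mean-spacing bookkeeping.
* **equilibrium** — Laplace vs ponderomotive pressure balance, stable radius,
  dissolved-gas budget *N<sub>L</sub>·K*.
* **dynamics** — charged Rayleigh–Plesset equation for radial oscillations in
  a weakly compressible viscous liquid, its closed-form eigenfrequency

      ω₀² = [5(P₀ − P_v) + 8Γ/R₀ − Q²/(8πεR₀⁴)] / [ρR₀²(1 + 4η/(c_s ρ R₀))]

  and attenuation, numerical integration, and ring-down extraction
  (zero-crossings + periodogram + log-envelope fits) as an internal oracle.
* **modes** — Legendre shape modes ξ(θ,t) = Σ αₙPₙ(cos θ)e^(−iωₙt) of the
  charged species, capillary mode frequencies, the Rayleigh fission parameter
  *Q*²/(16πΓ*R*³), and the electromagnetic intensity radiated by one
  oscillating charged species (∝ *Q*²β²/R⁷ for the quadrupole mode).
* **ensemble** — coherent two-population sample emission
  *I*₀ = (*Vn*₁*n<sub>b</sub>*)²*I*₁ + (*Vn*₂*n<sub>b</sub>*)²*I*₂ and the
  mapping of a measured size range to an emission band via ω₀(R).
* **synthetic** — seeded generators for DLS-like lognormal size distributions
  (mode ≈ 75 nm radius, FWHM 70–100 nm, 10⁹–10¹⁰ cm⁻³ shaken vs 5×10⁷ cm⁻³
  at rest) and radiometer-like group readings, plus the Student's t-test
  comparison (with Shapiro–Wilk / Bartlett diagnostics).

## Worked example

Shape-mode spectrum and emission of the reference species (|Q| = 60 e,
R = 75 nm, β₂ = 0.01):

```bash
$ bubston modes --n-max 3
[
  {
    "n": 2,
    "omega_full_per_s": 1439903079.0425966,
    "omega_uncharged_per_s": 1440987315.8513384,
    "intensity_W_m2": 2.8862157002031217e-31,
    "rayleigh_parameter": 0.0005365227041153224
  },
  {
    "n": 3,
    "omega_full_per_s": 2629111817.066591,
    ...
```

Reading: the quadrupole mode of a 75-nm species oscillates at
ω ≈ 1.44×10⁹ s⁻¹; its 60 charges soften that by <0.1% (the species sits at
5×10⁻⁴ of the Rayleigh fission threshold, deeply stable); a single species
radiates ≈ 2.9×10⁻³¹ W/m². Halving the radius at constant surface-charge
density raises this ×8 to ≈ 2.3×10⁻³⁰, and a coherent ensemble of k = 10
such bubbles gives k² × that ≈ 2.3×10⁻²⁸ W/m².

Synthetic pipeline (DLS distribution + radiometry + t-test):

```bash
$ bubston simulate --seed 1 --groups 1
pair 0: treated 2.092±0.177 vs reference 1.044±0.178  t=9.335 p=0.0000 significant=True
wrote size_distribution.csv and radiometry.csv
```

The treated group reads ≈ 2× the reference with n = 5 replicates, and the
Student's t-test flags the difference at p < 0.05 — the statistical contrast
the emission model is meant to explain.

Other subcommands: `bubston doublelayer`, `bubston equilibrium`,
`bubston dynamics`, `bubston ensemble` (see `--help`).

## Layout

```
src/bubston/     units, double_layer, equilibrium, dynamics, modes,
                 ensemble, synthetic, cli
tests/           pytest suite (unit, property and reproduction tests)
docs/methods.md  model assumptions, parameter defaults, numerical choices
```
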
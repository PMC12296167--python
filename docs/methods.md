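# Methods

This note records the model this package implements, the defaults it ships
with, and the numerical and design choices made where the formulation was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

All model equations are evaluated in CGS-Gaussian (electrostatic) units:
charge in esu, potential in statvolt, pressure in dyn/cm², energy in erg.
This choice avoids re-deriving 4πε₀ factors in the electrostatics; SI is
accepted and emitted only at I/O boundaries (`units.convert`,
`units.parse_quantity`, the CLI flags). Temperature is carried in energy
units (erg = k_B·kelvin); the default room temperature is **293.15 K**,
chosen so that the Bjerrum length in water (ε = 82) evaluates to 7.0 Å —
at 298 K it would be 6.8 Å. Frequencies are angular (s⁻¹) everywhere and are
reported on that scale; no 2π is inserted or removed anywhere, so a reader
comparing against cyclic-frequency instrument bands must divide by 2π
themselves. Radiated intensities are computed in erg s⁻¹ cm⁻² and reported
in W/m² (×10⁻³).

The permittivity is fixed at ε = 82 with no temperature or frequency
dispersion: every emission frequency handled here sits in the same GHz
window, so ε(ω) is a constant of the model, not a function.

## Double layer

The screening cloud is the linearized (Debye–Hückel) solution for a 1:1
electrolyte:

    φ(r) = Q e^{−κ(r−R_b)} / (ε(1+κR_b) r),
    ρ(r) = −κ²Q e^{−κ(r−R_b)} / (4π(1+κR_b) r),   κ² = 8π l_B n_is.

Only valence ±1 is supported — the linearized charge density
ρ = −2 n_is e² φ/T presumes a symmetric 1:1 electrolyte, and the API exposes
no valence parameter so other electrolytes cannot be expressed by accident. The profiles are
closed forms evaluated lazily on a caller-supplied grid; the diffuse layer
integrates to exactly −Q (the analytic antiderivative is exposed as
`DoubleLayerProfile.integrated_charge` and doubles as the quadrature oracle
in the tests). The linearization validity parameter e·|φ(R_b)|/T is computed
and attached to every profile; it is *reported, never enforced*, because the
model's interest extends to charges where it approaches 1. The dense (Stern)
part of the layer enters only as thickness bookkeeping
(`stern_thickness = a_c − R_b`, 25 nm for the default 100 nm hydrodynamic /
75 nm core radii); no field solution is attempted inside it.

## Equilibrium

Mechanical + diffusional equilibrium is encoded as P_in = P₀ with
2Γ/R_b = P_e = Q₀²/(8πεR_b⁴), giving R_b = [Q₀²/(16πεΓ)]^{1/3}. The
ponderomotive pressure is the closed-form derivative of the electrostatic
free energy with respect to the outer-layer volume; the finite-difference
check lives in the tests rather than in runtime code. With the thermodynamic
charge estimate Q₀ ~ 10⁴ e, ε = 82, Γ = 73 dyn/cm the formula gives
R_b ≈ 42.5 nm; the commonly quoted scale for these bubbles is ~100 nm. Both
statements are order-of-magnitude; the package returns the formula value and
applies no correction factor.

A consistency remark: a bubble *at* its own electro-capillary equilibrium has
Q²/(16πΓR_b³) = ε exactly, i.e. it sits above the (ε-free) charged-drop
fission threshold by the factor ε. The fission criterion and the equilibrium
balance are therefore reported independently and never combined.

## Radial dynamics

The charged Rayleigh–Plesset equation is implemented term by term as named
sub-expressions (module docstring of `dynamics.py` shows the full equation).
Three bracket placements in the source formulation were ambiguous; each was
resolved by requiring that (a) R = R₀, Ṙ = 0 be an exact rest state with no
drive and (b) the linearization about R₀ reproduce the closed-form
eigenfrequency exactly (which it does, with 3γ = 5 for γ = 5/3). The
closed-form attenuation coefficient implemented in `damping_coefficient` is
numerically ≈2× the amplitude decay rate of the linearized equation — it
tracks energy rather than amplitude decay — so the independent
`amplitude_decay_rate` is exposed alongside it and the ring-down envelope
test compares against the latter. At R₀ = 100 nm the attenuation gives a
decay time of ≈ 2.3 ns; a decay time of ≈ 4 µs has been quoted for the same
configuration and is not reproduced by this expression. Both numbers are
surfaced by the `dynamics` CLI summary; no agreement is forced.

Numerics: LSODA (stiff-capable, adaptive) at rtol 10⁻⁹ by default, state
nondimensionalized to (R/R₀, velocity per ns) and time in ns — at ω₀ ~ 10⁹
s⁻¹ on µs horizons this keeps all solver variables O(1). Ring-down tests
perturb by 1% of R₀ (linear regime, the same order as the shape-mode
amplitude ratio β_n ~ 0.01). Collapse (R < 0.01 R₀) terminates integration
with a structured error carrying the last valid state.

`extract_ringdown` estimates the damped frequency from zero-crossing
intervals (cross-checked against a Hann-windowed periodogram peak with
parabolic interpolation) and the amplitude decay rate from a log-envelope
fit over local extrema, ignoring the portion of the signal below 10⁻³ of the
peak deviation (integrator noise floor). These oscillators are heavily
damped (β/ω₀ up to ≈ 0.4 at R₀ = 50 nm), so the damped frequency lies up to
~7% below ω₀; the extractor therefore also reports the damping-corrected
natural frequency √(ω_d² + β²) — the standard modal-analysis identity —
which is the quantity comparable to the closed-form eigenfrequency. The
dual-estimator (zero-crossing vs periodogram) agreement contract applies in
the lightly damped regime; for heavily damped signals the periodogram peak
biases low and the zero-crossing estimate is primary.

## Shape modes and radiated intensity

Shape modes n ≥ 2 (n = 0 is the radial mode, n = 1 a translation) follow the
charged-sphere capillary dispersion

    ω_n0² = n(n+1)(n−1) [Γ(n+2)/R³ − Q²/(4πεR⁶)] / (nρ_l + (n+1)ρ_g)

whose charge term drives ω² through zero exactly at the Rayleigh fission
threshold (up to the medium permittivity, which the conventional threshold
Q²/(16πΓR³) ≥ 1 omits); a negative ω² raises an error carrying the squared
value rather than returning a NaN. The light-gas, zero-charge limit
ω_n0² = Γ(n+1)(n−1)(n+2)/(ρ_l R³) is exposed as the "uncharged" variant. At
n = 2, R = 75 nm, Γ = 73 dyn/cm this gives 1.44×10⁹ s⁻¹; a value of
4.2×10⁹ s⁻¹ has been quoted for the same configuration and is not reproduced
by the formula — the package reports the formula value.

The radiated intensity of a single species oscillating in mode n is

    I = Q² Γ^{n+1} β_n² / (4 ε(ω_n0) c^{2n+1} R^{n+5})
        × (n−1)(n+1)²(2n+1)² n^{n+1}
          / [ ((2n−1)!!)² (n+2)ⁿ (nρ_l + (n+1)ρ_g)^{n+1} ]

with c = c₀/√ε. The structure is that of electric multipole radiation of
order n (the ((2n−1)!!)⁻² suppression and c^{−(2n+1)} are the standard
multipole factors; Γ^{n+1}/ρ^{n+1} enters through the capillary dispersion
relation, and the density combination is the same two-fluid inertial weight
as in the mode frequency). ω_n0 appears only through ε(ω_n0): with the
Γ-based dispersion folded in, dimensional analysis leaves no free power of
ω — which is why the function takes ω_n0 as an explicit argument used for
the permittivity/labelling rather than recomputing it internally. For n = 2
the intensity scales as Q²β²/R⁷, so halving the radius at constant
surface-charge density (Q → Q/4) multiplies it by exactly 2³; coherent
ensembles of k in-phase oscillators gain k² (amplitudes add). Defaults:
β_n = 0.01, ρ_g/ρ_l = 10⁻³.

Higher modes are dramatically suppressed (≈13 orders of magnitude between
n = 2 and n = 3 at the reference configuration), so the quadrupole term is,
in practice, the emission.

The "intensity" of a single species is the formula value on a W/m² flux
scale; whether it is referenced to the species surface or to unit distance
is not defined by the underlying charged-drop result, and the package
reports it under the same label without adding an interpretation.

## Ensemble emission

The sample total is the coherent two-population estimate
I₀ = (Vn₁n_b)²I₁ + (Vn₂n_b)²I₂ with defaults V = 80 cm³ and n_b = 10¹⁰ cm⁻³,
quadratic in bubble counts by the in-phase assumption. Reports carry, next
to every computed number, the previously published reference estimates for
the same nominal configuration (`EmissionReport.reference`); direct
evaluation of the formula with the stated V and n_b exceeds the published
I₀ bounds by a factor of ≈80, and both numbers are therefore stated side by
side rather than reconciled. Phase desynchronization between oscillators is
acknowledged but not modelled. The emission band maps the *half-height*
radius range of the size distribution through ω₀(R) (monotonically
decreasing in R); the computed band for R ∈ (50, 95) nm is ≈0.85–2.15×10⁹
s⁻¹, wider than the published 1–1.4 GHz figure, and again both are carried.
A bin-by-bin coherent quadrature of the single-species emission over the
full distribution is included as `I0_integral_extension` and labelled an
extension — it goes beyond the two-population model.

## Synthetic data

The DLS generator samples radii from a lognormal — the minimal unimodal
positive-support family matching peaked, right-skewed measured size curves;
mode m and FWHM w fix the shape exactly via σ = asinh(w/2m)/√(2 ln 2),
μ = ln m + σ². Defaults describe a vigorously shaken sample: mode radius
75 nm, FWHM 85 nm (mid-range of the reported 70–100 nm), n_b = 10¹⁰ cm⁻³,
500 000 draws binned at 5 nm up to 400 nm. The shaking-force covariate maps
{0, 4, 8} → mode {60, 65, 75} nm, FWHM {70, 70, 100} nm, n_b
{5×10⁷, 10⁹, 10¹⁰} cm⁻³ — the monotone orderings (size and density grow with
treatment power) are the constrained features; the intermediate values are
this package's interpolation, chosen once. The generator works in gas-core
radius; a hydrodynamic-diameter view adds a 25 nm shell offset and doubles.

Radiometer readings are unitless synthetic intensities: reference ~ N(1,
0.2²), treated ~ N(ratio, (0.2·ratio)²), n = 5 replicates per group, clipped
at zero (a <10⁻⁶ perturbation at these noise levels). A coefficient of
variation of 0.2 represents a visibly noisy but decisive contrast at
ratio 2 and n = 5. `compare_groups` is the classical pooled-variance
Student's t-test with Shapiro–Wilk and Bartlett diagnostics reported, not
gated on.

What passing synthetic tests does and does not show: the generators
reproduce the *summary features* of the measured data (mode, width, density
orderings, group ratio with noise) — they do not emulate DLS autocorrelation
physics, instrument optics, flotation or dilution effects, and agreement of
the pipeline on synthetic data is a statement about the pipeline, not about
water.

All generators are pure functions of (config, seed); every stochastic test
in the suite is seeded.

## Problem sizes

Default test problem sizes — 12 oscillation periods per ring-down, 6000
trajectory samples, 500 000 generator draws, 10⁴ null pairs for the t-test
calibration — were chosen as the smallest sizes at which the respective
estimators are comfortably inside their tolerance bands, and are stated here
so that reruns at larger sizes are a one-line change.

## Known limitations

* Nonlinear Poisson–Boltzmann, ion-specific (Hofmeister) effects, and
  multivalent electrolytes are out of scope.
* The radial equation assumes sphericity; shape and radial dynamics are
  never coupled.
* The emission model adopts a charged-drop boundary treatment for a
  two-layer (liquid / charged shell) system; a three-layer
  (gas/shell/liquid) electromagnetic boundary-value solution is not
  attempted.
* Bubble generation/dissolution kinetics and acoustically driven rectified
  diffusion are not modelled.
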
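# Methods

## Scope and model structure

`biolumox` models firefly-luciferase photon emission as a function of
oxygen at two levels: a well-mixed reaction network (free enzyme, cell
lysate, intact cells in suspension) and a spatially resolved cell-seeded
hydrogel. The package also contains the three diffusion estimators and the
ratiometric oxygen-bead calibration that parameterise and validate the
transport side of the model, plus seeded generators that produce every
input the estimators consume.

### Well-mixed network

State variables (concentrations per total suspension volume, µM):
extracellular luciferin `L_ext`, intracellular luciferin `L_int`, active
enzyme `E`, cumulative photons. With cell density ρ (cells/ml), membrane
area `a` and cell volume `V_c` (sphere of diameter 15 µm by default), and
the intracellular volume fraction ε = ρ·V_c, the intracellular
*concentration* is l = L_int/ε and

    dL_ext/dt = −J,          J = P · a · ρ · (L_ext − l/φ)
    dL_int/dt = J − v,       v = E · v_unit(l, p)
    dE/dt     = −k(l, p) · E
    photon flux = quantum_yield · v  (scaled to photons/s by volume · N_A)

`v_unit(l, p)` is the per-enzyme Michaelis–Menten velocity with the
square-root oxygen interpolation between the endpoint affinities; for
lysate/free-solution contexts the network collapses to a single substrate
pool with no transport term. Oxygen enters *only* through the endpoint
Michaelis constants and the square-root interpolation of velocities —
there is no separate O2 Michaelis term in the light reaction, because
intermediate oxygen behaviour is defined empirically by that relation.
Decay constants are interpolated the same way between their hypoxic and
normoxic endpoint values, which reduces exactly to the per-condition
constants at 0 % and 21 % and gives the gel model a smooth local decay law.

Conservation: `L_ext + L_int + photons/quantum_yield` is invariant for a
closed system; the test suite checks it to better than 0.1 % and the
finite-volume gel solver conserves the same inventory (bath + gel +
photons) to machine precision by construction.

### The κ regime switch

Intact cells show two enzyme-inactivation regimes: fast while the
intracellular luciferin concentration is above a threshold κ
(diffusion-limited, substrate-rich) and slow below it
(transition-state-limited after substrate exhaustion). The switch is
implemented as a logistic blend of the two rate constants with width
`kappa_blend_width · κ`, defaulting to 0.01·κ. The narrow default is a
deliberate numerical choice: at the dense-cell flash conditions (below)
the intracellular luciferin settles only a few tens of µM under κ once
consumption has burnt the enzyme capacity, and a wide blend (e.g. 0.05·κ)
leaves the slow phase permanently inside the blend tail, biasing the
apparent slow rate upward by 7–15 %. With 0.01·κ the post-switch state
sits ≥ 8 blend widths below threshold and both asymptotic rates are clean.
κ = 0 pins the fast regime everywhere; κ above the attainable
intracellular concentration pins the slow regime, and both limits are
tested.

### Decay-rate units

The condition-specific inactivation constants (3948 and 1452 for lysates
at 21 %/0 % O2; 180, 27 and 3 for intact cells) are quoted in a nominal
"s⁻¹" unit whose literal reading is dimensionally inconsistent with
glow-type reactions lasting minutes to hours. They are therefore stored
verbatim in the quoted unit and converted internally by
`decay_unit_scale` (default 1e-6 s⁻¹ per printed unit), which places decay
times on the minute-to-hour scale consistent with the imaging cadences
modelled here. All fitting routines report rates in both the printed unit
and s⁻¹, so the convention is transparent and reversible.

### Default parameters

Endpoint affinities (42.6 / 938.4 µM), the 1.5× intact-cell crowding
factor, the five decay constants, the per-cell luciferase content
(0.92 amol), the 3.37 initial-velocity ratio criterion, the gel geometry
(8 mm × 2 mm, 1×10⁶ cells/ml, 47 µM bath luciferin in 2 ml medium) and
the acquisition geometries are fixed study conditions. The remaining
defaults are provisional, chosen once from field-typical values and the
structural requirements of the modelled scenarios:

| parameter | default | rationale |
|---|---|---|
| `v_max` (kcat) | 1.6 s⁻¹ | firefly-luciferase turnover at 25–37 °C |
| `kappa` | 400 µM | below the 470 µM assay concentration so the dense-cell flash traverses the switch; above it for the dilute assay so low-density traces stay in one regime |
| `permeability` | 0.3 µm/s | carrier-mediated luciferin uptake; equilibrates a 15 µm cell in ~10 s, fast relative to all decay times |
| `partition_coeff` | 1.0 | no net accumulation assumed in the absence of a measured gradient |
| `cell_diameter` | 15 µm | 293T in suspension |
| `c_sat` | 200 µM | dissolved O2 at 21 % / 37 °C in medium |
| `quantum_yield` | 0.41 | firefly bioluminescence quantum yield |
| `d_luciferin` | 350 µm²/s | agarose tracer value (fluorescein and beetle luciferin have near-identical molecular weight) |
| `d_oxygen` | 2000 µm²/s | small-solute diffusivity in 2 % agarose |
| OCR schedule | 60/40/25 amol·cell⁻¹·s⁻¹ (days 1–3) | declining respiration of gel-embedded 293T; day-1 value gives a ~110 µM centre-to-edge gradient at 1×10⁶ cells/ml |
| `k_o2` | 10 µM | respiration saturation constant |

Named scenarios: `lysate`/`solution` (0.1 nM enzyme, 470 µM luciferin,
110 µl), `cell` (1.09×10⁵ cells/ml — the density equivalent of 0.1 nM at
0.92 amol/cell), `cell-flash` (1×10⁷ cells/ml at 470 µM, the dense
adherent-layer condition whose trace is bi-exponential).

## Estimators

**Lineweaver–Burk** uses unweighted OLS on reciprocal coordinates
(Km = slope/intercept), because the quoted goodness-of-fit values refer to
the reciprocal-space line; exact on noise-free data, median |ΔKm| ≈ 7 %
under 5 % multiplicative noise (100 replicates).

**Exponential decay** is OLS on log flux (exact for a single exponential).

**Bi-exponential fitting** is iterative curve peeling: the slow component
is fitted where the fast component is extinct (< 2 % of the signal), the
fast branch by forward extension of an early seed fit until the trace
departs upward from its extrapolation. A global log-residual least-squares
refinement of A₁e^(−k₁t) + A₂e^(−k₂t) is adopted only when the sum model
shows no systematic lack of fit (smoothed residual criterion). This matters
because a regime-switch trace is piecewise-exponential: its knee is sharper
than any two-exponential sum, and a naive global fit biases the fast rate
by tens of percent while the peeled asymptotic slopes are accurate to
< 1 %. Rate ratios below 2 are declared degenerate and returned as a
mono-exponential with a warning.

**Initial-velocity extrapolation** fits both traces of a normoxic/hypoxic
pair with exponentials and solves (by bracketed root finding on the log
ratio) for the time point where their ratio equals the configured
criterion (3.37); without a pair, t₀ = 0.

**FRAP** normalises frames by the prebleach image (flat-field), circularly
averages the bleach deficit in 0.5-pixel radial bins, and applies a
zero-order Hankel transform by trapezoidal quadrature. Frames whose total
deficit mass has dropped more than 10 % from the first frame are excluded
(the spreading profile is leaving the field of view and its transform is
truncation-biased). Frequencies are kept while their initial amplitude
exceeds 10 % of the band maximum and at least four frames remain above an
amplitude floor; the headline D pools the lowest third of that band
(highest SNR) in a log-linear regression, with per-frequency estimates
retained for the Brownian frequency-independence check. The estimator is
accurate to < 1.5 % on noise-free Gaussian-spreading stacks across
D ∈ [50, 700] µm²/s; the immobile fraction is fixed at zero. The bleach
spot is modelled as a Gaussian with σ₀ = radius/2 (the spot radius read as
its 2σ extent).

**FCS** fits the anomalous 3D autocorrelation by least squares; with
α fixed at 1 it is the standard free-diffusion form, and generator/fitter
share the closed form so zero-noise round trips are exact. Calibration on
a reference dye of known D requires the fitted α within 0.1 of 1 and sets
w_xy = √(4 D τ_D); no triplet-state term is included.

**Gradient profiles** are fitted jointly over all times with
C/C0 = A·erfc(x/(2√(Dt))); A is free by default (scale invariance) or can
be pinned to 1 when C0 is known. The finite-source checker solves the
same problem with a depleting well-mixed source compartment (1D finite
volume) and reports the maximum deviation from the semi-infinite solution
over the observation window; with C0 pinned, source depletion biases the
fitted D low, as expected.

**OCR estimation** least-squares fits the steady radial oxygen profile
(one scalar OCR per culture day, log-parameterised) to measured profiles,
initialised from the parabolic zero-order depth formula
ΔO = Q R²/(4D). Median error < 10 % at 5 % noise (50 replicates).

**Peak analysis** fits a Gaussian to the contiguous region above half
maximum (FWHM = 2√(2 ln 2) σ) and an exponential to the tail beyond twice
the peak time. **Oxygen inversion** projects a query (t_peak, FWHM, decay
rate), normalised by the library spread, onto the segment between the
nearest library entries and interpolates their mean-O2 labels, refusing
queries outside the library hull.

## Gel solver numerics

Cell-centred finite volumes on a uniform radial grid (default 101 nodes;
tests use 31–62), face-centred fluxes, zero flux at the axis (no
singularity arises because the axis is a face, not a node), Dirichlet rim
for oxygen, and a mass-conserving Robin-type exchange with the finite bath
for luciferin (the rim face flux debits the bath ODE directly). Method of
lines with LSODA at rtol 1e-8 / atol 1e-12. Halving the grid step changes
the averaged trace by < 1 %. With respiration off, fast mixing and a
pre-equilibrated gel, the averaged trace reproduces the well-mixed cell
simulation to < 0.01 %, confirming the coupling reduces correctly.
Top-view rendering maps the axisymmetric flux density to a disk image
(per-pixel photons·s⁻¹·cm⁻², optionally per steradian over 4π for
radiance); the image integral matches the radial quadrature to < 1 % at
the default pixel size.

## Synthetic data: what it does and does not emulate

Generators reproduce the deterministic structure each estimator assumes —
Michaelis–Menten titrations, ODE/PDE traces on the documented imaging
cadence (5-min/10-min/30-min intervals, 74 samples over 12 h), Gaussian
bleach spots spreading as σ²(t) = σ₀² + 2Dt on the documented FRAP
geometry (256² px, 0.497 µm, 72 ms), closed-form FCS curves, and
volume-uniform bead positions read through the Stern–Volmer forward
model. Noise defaults are mean-preserving multiplicative log-normal (5 %)
for fluxes/velocities and additive Gaussian for images.

Not emulated: camera photophysics (EM gain, read-noise spectra), photon
scattering/absorption in the gel, discrete single-cell heterogeneity,
luciferase expression dynamics, HIF-1 transcriptional responses, and the
ATP/L-AMP/CoA inhibition chemistry (whose net effects are absorbed into
the context-specific v_max and decay constants). Passing round-trip tests
therefore demonstrates estimator correctness under the stated model, not
robustness to instrument artefacts absent from the generators.

## Problem sizes

The default test run and the acceptance script use deliberately compact
problems — 31–62 radial nodes, 30–120 time samples, 40-frame FRAP stacks,
140-point FCS curves, 50–100 noise replicates — which keep the full suite
under half a minute while leaving every tolerance comfortably met; the
grid-convergence test documents that these sizes are in the converged
regime.

## Known limitations

* The absolute scale of the decay-constant unit is a convention
  (`decay_unit_scale`); only ratios and per-condition comparisons are
  physically meaningful until the unit is pinned externally.
* κ, kcat, permeability, partition coefficient, OCR schedule and k_O2 are
  provisional defaults (table above), not fitted to data.
* The Stern–Volmer model is linear single-site quenching; multi-site
  models and photobleaching/temperature compensation are out of scope.
* The gel model is 1D radial; any axial leakage or meniscus effect in a
  real assembly violates the confinement assumption.
* The oxygen-inversion library interpolates locally and refuses
  extrapolation; it is only as good as the span and spacing of the
  simulated library.
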
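# biolumox

Quantitative modelling of the oxygen dependence of firefly-luciferase
bioluminescence, for researchers who use bioluminescence imaging to monitor
cells in 3D culture and need to separate *how many active cells are there*
from *how much oxygen do they see*.

Bioluminescence imaging reads out luciferase activity, but the light
reaction consumes O2: the emitted photon flux confounds reporter abundance
with local oxygen. `biolumox` implements a tested bioluminescence–oxygen
model that simulates photon-flux kinetics in well-mixed reactions and in
cell-seeded cylindrical hydrogels, and inverts measured signals (kinetic
titrations, decay traces, FRAP/FCS/gradient diffusion data, ratiometric
oxygen-bead intensities, emission-peak parameters) back to the model's
parameters — including the local oxygen concentration.

## The model

**Well-mixed kinetics.** The light reaction follows Michaelis–Menten
kinetics in luciferin with an oxygen-dependent apparent affinity,

    v = V_max · S / (K_m(O2) + S),

with endpoint constants K_m,21 = 42.6 µM (normoxia, 21 % O2) and
K_m,0 = 938.4 µM (hypoxia), an additional 1.5-fold K_m increase in intact
cells (cytoplasmic crowding), and a square-root interpolation of initial
velocities at intermediate oxygen,

    v(S, p) = v(S, 0) + sqrt(p / 21) · [v(S, 21) − v(S, 0)].

Active enzyme E decays first order, dE/dt = −k E, at a condition-specific
rate; in intact cells the rate switches between a fast and a slow regime as
the intracellular luciferin concentration crosses a threshold κ
(substrate-rich, diffusion-limited → substrate-poor,
transition-state-limited). Intact cells exchange luciferin with the medium
through a lumped membrane permeability P with an equilibrium partition
coefficient φ:

    J_mem = P · a_cell · (L_ext − L_int/φ).

Photon flux is the quantum yield times the reaction velocity, so cumulative
photons track luciferin consumption exactly (a conservation law the test
suite enforces).

**Hydrogel reaction–diffusion.** An axially confined cylindrical gel
(8 mm × 2 mm, axisymmetric → 1D radial) couples oxygen
diffusion–consumption (per-cell Michaelis–Menten respiration with per-day
maximal OCR), luciferin diffusion from a finite well-mixed bath, per-node
membrane uptake, and the local kinetics above. The solver is a conservative
finite-volume method of lines with a stiff integrator.

**Diffusion estimators.** Tracer diffusivity enters the transport model and
is measured three independent ways: spatial-frequency FRAP (Hankel-domain
regression, every mode decays as exp(−D k² t)), FCS with the anomalous 3D
autocorrelation model G(τ) = ⟨N⟩⁻¹[1+(τ/τ_D)^α]⁻¹[1+(τ/τ_D)^α/ω²]^(−1/2),
and semi-infinite erfc penetration profiles, C/C0 = erfc(x / (2√(Dt))).

**Oxygen sensing.** Ratiometric microbeads obey the Stern–Volmer relation
r0/r = 1 + K_sv [O2]; a two-point (0 %/21 %) calibration fully determines
the read-out.

## Worked example

Recover the normoxic Michaelis constant from a synthetic titration, then
simulate a dense intact-cell reaction at 470 µM luciferin and fit its
bi-exponential decay:

```python
import numpy as np
from biolumox import (KineticConfig, simulate_batch_reaction,
                      fit_biexponential, lineweaver_burk)
from biolumox.synthetic_data import gen_velocity_dataset

cfg = KineticConfig()
ds = gen_velocity_dataset(cfg, [10, 30, 100, 300, 600, 1000],
                          cfg.oxygen(21.0), "lysate")
fit = lineweaver_burk(ds)
print(f"Km = {fit['km']:.1f} uM, Vmax = {fit['vmax']:.2f} /s, "
      f"r^2 = {fit['r_squared']:.3f}")

t = np.unique(np.concatenate([np.linspace(1, 2.5e4, 600),
                              np.linspace(2.5e4, 1.4e5, 300)]))
res = simulate_batch_reaction(cfg, {"luciferin_um": 470.0,
                                    "cells_per_ml": 1.0e7}, t, "cell")
print(f"peak flux = {res.trace.flux.max():.3g} photons/s")
fb = fit_biexponential(res.trace)
print(f"fast rate = {fb['rate_fast']:.1f}, slow rate = {fb['rate_slow']:.2f}"
      f" (printed unit), split at t = {fb['split_time']:.0f} s")
```

Output:

```
Km = 42.6 uM, Vmax = 1.60 /s, r^2 = 1.000
peak flux = 3.49e+11 photons/s
fast rate = 179.8, slow rate = 27.04 (printed unit), split at t = 11652 s
```

The titration lies exactly on the configured curve, so the
double-reciprocal fit returns K_m,21 = 42.6 µM. The dense-cell trace
traverses the κ regime switch: the fitted fast and slow rates recover the
configured enzyme-decay constants (180 and 27 in the reported decay unit;
rates are stored verbatim in that unit and converted internally through a
configurable scale, see `docs/methods.md`).

A `biolumox` command-line entry point wraps the same operations
(`simulate-batch`, `fit-kinetics`, `simulate-gel`, `frap`, `fcs`,
`gradient-fit`, `calibrate-osb`, `oxygen-profile`, `gen-*`, `run`); every
pipeline run writes a manifest with seeds and output checksums.

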
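"""Seeded generators for every input the analysis pipeline consumes.

Each generator produces data with the statistical structure its estimator
assumes, under the experimental conditions being emulated (assay volumes,
acquisition cadences, imaging geometry).  At zero noise every generator is
the exact inverse of its estimator, which the test suite exploits for
round-trip parameter recovery; with noise, the default is 5 % multiplicative
log-normal error on fluxes/velocities (mean-preserving) and additive
Gaussian error at SNR ~ 20 on images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import (BATH_LUCIFERIN_UM, D_FCS_AGAROSE, D_LUCIFERIN_GEL,
                     CellField, GelGeometry, KineticConfig, OxygenLevel)
from .diffusion_inference import FcsCurve, FcsParams, FrapSeries, fcs_model
from .kinetics import (LuminescenceTrace, VelocityDataset,
                       interpolate_velocity_oxygen, simulate_batch_reaction)
from .oxygen_sensing import BeadReadout, SternVolmerCalibration

__all__ = [
    "NoiseSpec",
    "default_ivis_schedule",
    "gen_velocity_dataset",
    "gen_luminescence_trace",
    "gen_frap_stack",
    "gen_fcs_curve",
    "gen_oxygen_readouts",
    "SCENARIOS",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model applied by the generators.

    ``multiplicative-lognormal``: each value is multiplied by a
    mean-preserving log-normal factor with relative sd ``level``.
    ``additive-gaussian``: Gaussian noise with sd ``level`` (absolute).
    ``poisson``: values are Poisson counts at ``value * level`` rescaled
    back (``level`` plays the role of counts per unit).
    """

    model: str = "multiplicative-lognormal"
    level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.model not in ("multiplicative-lognormal", "additive-gaussian",
                              "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray,
              rng: np.random.Generator | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.level == 0:
            return values.copy()
        rng = rng or self.rng()
        if self.model == "multiplicative-lognormal":
            sigma = math.sqrt(math.log1p(self.level ** 2))
            factor = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                   size=values.shape)
            return values * factor
        if self.model == "additive-gaussian":
            return values + rng.normal(0.0, self.level, size=values.shape)
        # poisson
        return rng.poisson(np.maximum(values, 0.0) * self.level) / self.level


NOISELESS = NoiseSpec(level=0.0)

#: named batch scenarios: (context, initial conditions, oxygen percent)
SCENARIOS = {
    "lysate": ("lysate", {"luciferin_um": 470.0, "enzyme_nM": 0.1}, 21.0),
    "solution": ("solution", {"luciferin_um": 470.0, "enzyme_nM": 0.1}, 21.0),
    # dynamic time-point assay density equivalent to 0.1 nM free enzyme
    "cell": ("cell", {"luciferin_um": 470.0, "cells_per_ml": 1.09e5}, 21.0),
    # dense adherent layer at 470 µM: traverses the kappa regime switch
    "cell-flash": ("cell", {"luciferin_um": 470.0, "cells_per_ml": 1.0e7},
                   21.0),
}


def default_ivis_schedule() -> np.ndarray:
    """Imaging cadence of the gel validation runs, in seconds.

    5-min intervals for 3 h, then 10-min for 5 h, then 30-min for 4 h
    (36 + 30 + 8 = 74 samples).
    """
    a = 300.0 * np.arange(1, 37)                       # 5 min .. 3 h
    b = a[-1] + 600.0 * np.arange(1, 31)               # .. 8 h
    c = b[-1] + 1800.0 * np.arange(1, 9)               # .. 12 h
    return np.concatenate([a, b, c])


def gen_velocity_dataset(config: KineticConfig, substrate_levels,
                         oxygen: OxygenLevel, context: str = "lysate",
                         noise: NoiseSpec = NOISELESS) -> VelocityDataset:
    """Initial-velocity titration on the oxygen-dependent MM curve.

    Noise-free output lies exactly on the curve; endpoint oxygen uses the
    endpoint Michaelis constant, intermediate oxygen the square-root
    interpolation.
    """
    s = np.asarray(substrate_levels, dtype=float)
    if s.size == 0:
        raise ValueError("substrate level list is empty")
    v = np.array([interpolate_velocity_oxygen(si, oxygen.percent, config,
                                              context) for si in s])
    v_noisy = noise.apply(v)
    return VelocityDataset(substrate_conc=s, velocity=np.maximum(v_noisy, 0.0),
                           oxygen=oxygen, context=context)


def gen_luminescence_trace(config: KineticConfig, scenario: str = "lysate",
                           sampling=None, noise: NoiseSpec = NOISELESS,
                           oxygen_percent: float | None = None,
                           **overrides) -> LuminescenceTrace:
    """Photon-flux trace from a named batch scenario plus noise.

    ``sampling`` is an explicit time grid in seconds or None for the
    default imaging cadence; scenario initial conditions can be overridden
    by keyword (``luciferin_um``, ``enzyme_nM``, ``cells_per_ml``,
    ``volume_ml``).  ``gel-average`` runs the full hydrogel model and is
    provided by :func:`biolumox.reaction_diffusion.solve_coupled_bioluminescence`;
    here it uses a reduced grid suitable for trace-level work.
    """
    if sampling is None:
        time_grid = default_ivis_schedule()
    else:
        time_grid = np.asarray(sampling, dtype=float)

    if scenario == "gel-average":
        from .reaction_diffusion import solve_coupled_bioluminescence
        geometry = overrides.pop("geometry", GelGeometry())
        cells = overrides.pop("cells", CellField())
        _, trace = solve_coupled_bioluminescence(
            geometry, cells, config, t_span=float(time_grid[-1]),
            boundary_luciferin=overrides.pop("luciferin_um",
                                             BATH_LUCIFERIN_UM),
            n_r=overrides.pop("n_r", 41),
            n_t=overrides.pop("n_t", 80), **overrides)
        flux = np.interp(time_grid, trace.time, trace.flux)
        clean = LuminescenceTrace(time_grid, flux, condition="gel-average",
                                  initial_substrate=trace.initial_substrate)
    elif scenario in SCENARIOS:
        context, initial, pct = SCENARIOS[scenario]
        initial = {**initial, **overrides}
        if oxygen_percent is not None:
            pct = oxygen_percent
        res = simulate_batch_reaction(config, initial, time_grid, context,
                                      config.oxygen(pct))
        clean = res.trace
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    flux = np.maximum(noise.apply(clean.flux), 0.0)
    return LuminescenceTrace(clean.time, flux, clean.condition, clean.oxygen,
                             clean.initial_substrate)


def gen_frap_stack(d: float = D_LUCIFERIN_GEL, n_frames: int = 40,
                   shape: tuple[int, int] = (256, 256),
                   pixel_size: float = 0.497, frame_interval: float = 0.072,
                   bleach_radius: float = 10.0, bleach_depth: float = 0.6,
                   baseline: float = 1000.0, illumination_gradient: float = 0.1,
                   noise: NoiseSpec = NOISELESS) -> FrapSeries:
    """Synthetic bleach-recovery stack under free 2D diffusion.

    Frame 0 carries a Gaussian bleach deficit with sigma0 = radius/2 (the
    spot radius taken as its 2-sigma extent); subsequent frames follow the
    analytic Gaussian spreading sigma^2(t) = sigma0^2 + 2 D t with the
    deficit integral conserved.  A mild linear illumination gradient is
    baked into both prebleach and frames so that prebleach normalisation is
    exercised.  ``noise`` (additive Gaussian, level relative to baseline)
    is applied per pixel.
    """
    if d < 0:
        raise ValueError("diffusivity must be non-negative")
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    sigma0 = bleach_radius / 2.0
    if bleach_radius / pixel_size > min(cy, cx):
        raise ValueError("bleach spot extends outside the frame")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * pixel_size ** 2
    illum = 1.0 + illumination_gradient * (xx - cx) / nx
    prebleach = baseline * illum

    rng = noise.rng()
    frames = np.empty((n_frames, ny, nx))
    for i in range(n_frames):
        s2 = sigma0 ** 2 + 2.0 * d * i * frame_interval
        deficit = bleach_depth * (sigma0 ** 2 / s2) * np.exp(-r2 / (2.0 * s2))
        frame = prebleach * (1.0 - deficit)
        if noise.level > 0:
            if noise.model == "additive-gaussian":
                frame = frame + rng.normal(0.0, noise.level * baseline,
                                           size=frame.shape)
            else:
                frame = noise.apply(frame, rng)
        frames[i] = np.maximum(frame, 0.0)
    return FrapSeries(frames=frames, prebleach=prebleach,
                      pixel_size=pixel_size, frame_interval=frame_interval,
                      bleach_center=(cy, cx), bleach_radius=bleach_radius)


def gen_fcs_curve(params: FcsParams, lag_grid=None,
                  noise: NoiseSpec = NOISELESS) -> FcsCurve:
    """Autocorrelation curve from the anomalous-diffusion closed form."""
    if lag_grid is None:
        lag_grid = np.logspace(-6, 1, 140)
    lag = np.asarray(lag_grid, dtype=float)
    g = fcs_model(lag, params.n_mean, params.tau_d, params.alpha,
                  params.omega)
    return FcsCurve(lag=lag, g=noise.apply(g))


def fcs_curve_for_d(d: float = D_FCS_AGAROSE, w_xy: float = 0.25,
                    n_mean: float = 2.0, alpha: float = 1.0,
                    omega: float = 5.0, lag_grid=None,
                    noise: NoiseSpec = NOISELESS) -> FcsCurve:
    """Convenience wrapper: curve whose diffusive time encodes D."""
    tau_d = w_xy ** 2 / (4.0 * d)
    return gen_fcs_curve(FcsParams(n_mean=n_mean, tau_d=tau_d, alpha=alpha,
                                   omega=omega, w_xy=w_xy), lag_grid, noise)


def gen_oxygen_readouts(field, cal: SternVolmerCalibration, n_beads: int = 200,
                        radius_mm: float = 4.0, i_reference: float = 1000.0,
                        noise: NoiseSpec = NOISELESS) -> list[BeadReadout]:
    """Ratiometric bead read-outs sampled from a radial oxygen field.

    ``field`` maps radial position (mm) to dissolved O2 (µM).  Bead
    positions are uniform in gel volume (density proportional to r in the
    radial histogram); the sensitive-channel intensity follows the
    Stern-Volmer quench of the truth field, with per-channel noise.
    """
    rng = noise.rng()
    r = radius_mm * np.sqrt(rng.uniform(0.0, 1.0, size=n_beads))
    o2 = np.array([max(float(field(ri)), 0.0) for ri in r])
    ratio = cal.r0 / (1.0 + cal.ksv * o2)
    i_ref = np.full(n_beads, i_reference)
    i_sens = ratio * i_ref
    if noise.level > 0:
        i_sens = np.maximum(noise.apply(i_sens, rng), 1e-9)
        i_ref = np.maximum(noise.apply(i_ref, rng), 1e-9)
    return [BeadReadout(i_sensitive=float(s), i_reference=float(fr),
                        roi_id=i, position_mm=float(ri))
            for i, (s, fr, ri) in enumerate(zip(i_sens, i_ref, r))]
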
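"""Well-mixed kinetics of the firefly bioluminescence reaction.

The light reaction converts luciferin + ATP + O2 into oxyluciferin and a
photon, catalysed by firefly luciferase.  Oxygen availability enters through
the apparent Michaelis constant of the luciferin saturation curve -- high
affinity (Km,21 = 42.6 µM) at atmospheric oxygen, low affinity
(Km,0 = 938.4 µM) under hypoxia -- and initial velocities at intermediate
oxygen follow a square-root interpolation between the two endpoints.  The
active enzyme pool decays first-order at a condition-specific rate; in
intact cells the rate switches between a fast (substrate-rich,
diffusion-limited) and a slow (substrate-poor, transition-state-limited)
regime as the intracellular luciferin concentration crosses the threshold
``kappa``.  Intact cells additionally exchange luciferin with the medium
across the membrane through a lumped permeability with an equilibrium
partition coefficient.

The module provides the forward ODE model (lysate / free solution / intact
cells) and the estimators that invert measured traces and velocity datasets
back to the model parameters: exponential and bi-exponential decay fits,
double-reciprocal (Lineweaver-Burk) Michaelis-Menten fits, and the
ratiometric initial-time-point extrapolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import (AVOGADRO, NORMOXIC_PERCENT, KineticConfig, OxygenLevel,
                     SolverOptions)

__all__ = [
    "VelocityDataset",
    "LuminescenceTrace",
    "BatchResult",
    "DegenerateFitWarning",
    "michaelis_menten_velocity",
    "interpolate_velocity_oxygen",
    "simulate_batch_reaction",
    "fit_exponential_decay",
    "fit_biexponential",
    "extrapolate_initial_velocity",
    "lineweaver_burk",
    "equivalent_cell_density",
    "cell_decay_rate",
    "lysate_decay_rate",
]


class DegenerateFitWarning(UserWarning):
    """Emitted when a bi-exponential fit collapses to a single component."""


@dataclass(frozen=True)
class VelocityDataset:
    """Initial-velocity measurements over a luciferin titration."""

    substrate_conc: np.ndarray   # µM
    velocity: np.ndarray         # same units as v_max
    oxygen: OxygenLevel
    replicate_sd: np.ndarray | None = None
    context: str = "lysate"

    def __post_init__(self):
        object.__setattr__(self, "substrate_conc",
                           np.asarray(self.substrate_conc, dtype=float))
        object.__setattr__(self, "velocity",
                           np.asarray(self.velocity, dtype=float))
        s, v = self.substrate_conc, self.velocity
        if s.shape != v.shape:
            raise ValueError("substrate_conc and velocity must match in length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if len(np.unique(s)) != len(s):
            raise ValueError("substrate concentrations must be distinct")
        if np.any(v < 0):
            raise ValueError("velocities must be non-negative")
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            if sd.shape != s.shape:
                raise ValueError("replicate_sd length mismatch")
            object.__setattr__(self, "replicate_sd", sd)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"conc_uM": self.substrate_conc,
                           "velocity": self.velocity})
        if self.replicate_sd is not None:
            df["sd"] = self.replicate_sd
        return df


@dataclass(frozen=True)
class LuminescenceTrace:
    """Time-stamped photon-flux trace with condition metadata."""

    time: np.ndarray             # s, strictly increasing
    flux: np.ndarray             # photons s^-1 (or radiance units), >= 0
    condition: str = "lysate"    # lysate | cell | solution | gel-average
    oxygen: OxygenLevel | None = None
    initial_substrate: float | None = None  # µM

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "flux", np.asarray(self.flux, dtype=float))
        t, f = self.time, self.flux
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time and flux must be matched 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(f < -0.0):
            raise ValueError("flux must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    def window(self, t_min: float = -np.inf, t_max: float = np.inf
               ) -> "LuminescenceTrace":
        m = (self.time >= t_min) & (self.time <= t_max)
        return LuminescenceTrace(self.time[m], self.flux[m], self.condition,
                                 self.oxygen, self.initial_substrate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "flux": self.flux})


@dataclass(frozen=True)
class BatchResult:
    """Trace plus full state history from a batch simulation."""

    trace: LuminescenceTrace
    history: pd.DataFrame        # columns: time_s, luciferin_ext, ...


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------

def michaelis_menten_velocity(substrate: float, oxygen: OxygenLevel,
                              config: KineticConfig,
                              context: str = "lysate") -> float:
    """Reaction velocity v = v_max * S / (K + S) at an oxygen endpoint.

    ``K`` is the endpoint Michaelis constant for the oxygen level (21 % or
    ~0 %), multiplied by the crowding factor for intact cells.  Velocity is
    per enzyme amount (same units as ``config.v_max``).
    """
    substrate = np.asarray(substrate, dtype=float)
    if np.any(substrate < 0):
        raise ValueError("substrate concentration must be non-negative")
    k = config.km(oxygen, context)
    v = config.v_max * substrate / (k + substrate)
    return v if v.ndim else float(v)


def interpolate_velocity_oxygen(substrate: float, oxygen_percent: float,
                                config: KineticConfig,
                                context: str = "lysate") -> float:
    """Initial velocity at intermediate oxygen via square-root interpolation.

    v(S, p) = v(S, 0) + sqrt(p/21) * (v(S, 21) - v(S, 0)); exact at both
    endpoints and monotone non-decreasing in p.
    """
    p = np.asarray(oxygen_percent, dtype=float)
    if np.any(p < 0) or np.any(p > NORMOXIC_PERCENT):
        raise ValueError("oxygen percent must lie in [0, 21]")
    v_hyp = michaelis_menten_velocity(substrate, config.oxygen(0.0),
                                      config, context)
    v_norm = michaelis_menten_velocity(substrate, config.oxygen(21.0),
                                       config, context)
    out = v_hyp + np.sqrt(p / NORMOXIC_PERCENT) * (v_norm - v_hyp)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# decay-rate regimes
# ---------------------------------------------------------------------------

def lysate_decay_rate(oxygen_percent: float, config: KineticConfig) -> float:
    """Lysate/free-enzyme inactivation rate in s^-1 at a given oxygen level.

    Endpoint constants are square-root interpolated like the velocities.
    """
    s = config.decay_unit_scale
    k_hyp = config.decay_lysate_hypoxic * s
    k_norm = config.decay_lysate_normoxic * s
    w = np.sqrt(np.clip(oxygen_percent, 0.0, NORMOXIC_PERCENT)
                / NORMOXIC_PERCENT)
    return k_hyp + w * (k_norm - k_hyp)


def cell_decay_rate(l_int: float, oxygen_percent: float,
                    config: KineticConfig) -> float:
    """Intact-cell enzyme inactivation rate in s^-1.

    Under normoxia the rate blends logistically (width 0.05*kappa) between
    the fast regime above the intracellular-luciferin threshold ``kappa``
    and the slow regime below it; kappa = 0 pins the fast regime
    everywhere.  The normoxic regime rate is then square-root interpolated
    against the single hypoxic constant.
    """
    s = config.decay_unit_scale
    k_fast = config.decay_cell_fast_normoxic * s
    k_slow = config.decay_cell_slow_normoxic * s
    if config.kappa <= 0.0:
        k_norm = k_fast * np.ones_like(np.asarray(l_int, dtype=float))
    else:
        width = config.kappa_blend_width * config.kappa
        z = np.clip((np.asarray(l_int, dtype=float) - config.kappa) / width,
                    -60.0, 60.0)
        sigma = 1.0 / (1.0 + np.exp(-z))
        k_norm = k_slow + (k_fast - k_slow) * sigma
    k_hyp = config.decay_cell_hypoxic * s
    w = np.sqrt(np.clip(oxygen_percent, 0.0, NORMOXIC_PERCENT)
                / NORMOXIC_PERCENT)
    out = k_hyp + w * (k_norm - k_hyp)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def cell_reaction_rates(l_ext, l_int_total, enzyme, oxygen_percent,
                        cells_per_ml, config: KineticConfig):
    """Per-total-volume rates of the intact-cell reaction network.

    All concentrations are expressed per total suspension volume (µM);
    ``l_int_total`` is the intracellular luciferin amount per total volume,
    which divided by the intracellular volume fraction gives the
    concentration seen by the enzyme and by the kappa switch.  Returns
    ``(j_mem, v, k_dec, l_int_conc)`` where ``j_mem`` is the membrane influx
    and ``v`` the photon-generating velocity, both in µM s^-1 total volume.

    Shared by the batch integrator and by the per-node kinetics of the
    hydrogel reaction-diffusion model.
    """
    rho_um3 = np.asarray(cells_per_ml, dtype=float) / 1e12  # cells per µm^3
    eps = rho_um3 * config.cell_volume     # intracellular volume fraction
    if np.any(eps <= 0):
        raise ValueError("cells_per_ml must be positive in cell context")
    l_int_conc = l_int_total / eps
    j_mem = (config.permeability * config.cell_area * rho_um3
             * (l_ext - l_int_conc / config.partition_coeff))
    v_unit = interpolate_velocity_oxygen(np.maximum(l_int_conc, 0.0),
                                         oxygen_percent, config, "cell")
    v = enzyme * v_unit
    k_dec = cell_decay_rate(l_int_conc, oxygen_percent, config)
    return j_mem, v, k_dec, l_int_conc


def simulate_batch_reaction(config: KineticConfig, initial: dict,
                            time_grid: Sequence[float],
                            context: str = "lysate",
                            oxygen: OxygenLevel | None = None,
                            solver: SolverOptions | None = None
                            ) -> BatchResult:
    """Integrate the well-mixed bioluminescence reaction.

    Parameters
    ----------
    initial
        ``luciferin_um`` (extracellular, µM) plus either ``enzyme_nM``
        (lysate/solution) or ``cells_per_ml`` (cell context); optional
        ``volume_ml`` (default 0.11, the 10 µl + 100 µl assay mix).
    time_grid
        Strictly increasing sample times in seconds (first may be 0).
    oxygen
        Constant oxygen level (default normoxia).

    Returns the photon-flux trace and the full state history.  Photon flux
    is ``quantum_yield x reaction velocity`` scaled to photons/s for the
    reaction volume.  States stay non-negative and the closed system
    conserves luciferin + photons/quantum_yield.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 2 or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing with >= 2 points")
    if oxygen is None:
        oxygen = config.oxygen(NORMOXIC_PERCENT)
    solver = solver or SolverOptions()
    l0 = float(initial.get("luciferin_um", 0.0))
    if l0 < 0:
        raise ValueError("initial luciferin must be non-negative")
    volume_ml = float(initial.get("volume_ml", 0.11))
    # µM µm^-3 ... photons: µM * L * 1e-6 mol/µM-L * N_A
    photon_factor = volume_ml * 1e-3 * 1e-6 * AVOGADRO
    p = oxygen.percent

    if context in ("lysate", "solution"):
        e0 = float(initial.get("enzyme_nM", 0.1)) * 1e-3  # µM
        k_dec = lysate_decay_rate(p, config)

        def rhs(t, y):
            l, e, _ = y
            v = e * interpolate_velocity_oxygen(max(l, 0.0), p, config,
                                                context)
            return [-v, -k_dec * e, config.quantum_yield * v]

        y0 = [l0, e0, 0.0]
        labels = ["luciferin", "enzyme", "photons_um"]
    elif context == "cell":
        cells_per_ml = float(initial.get("cells_per_ml", 0.0))
        if cells_per_ml <= 0:
            raise ValueError("cell context requires cells_per_ml > 0")
        e0 = config.enzyme_um_per_cell_density(cells_per_ml)

        def rhs(t, y):
            l_ext, l_int, e, _ = y
            j, v, k_dec, _ = cell_reaction_rates(
                max(l_ext, 0.0), max(l_int, 0.0), e, p, cells_per_ml, config)
            return [-j, j - v, -k_dec * e, config.quantum_yield * v]

        y0 = [l0, 0.0, e0, 0.0]
        labels = ["luciferin_ext", "luciferin_int", "enzyme", "photons_um"]
    else:
        raise ValueError(f"unknown context {context!r}")

    t0 = min(0.0, time_grid[0])
    sol = solve_ivp(rhs, (t0, time_grid[-1]), y0, method="LSODA",
                    t_eval=time_grid, rtol=solver.rtol, atol=solver.atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"batch integration failed: {sol.message}")

    y = np.clip(sol.y, 0.0, None)
    if context == "cell":
        flux = np.empty(len(time_grid))
        for i in range(len(time_grid)):
            _, v, _, _ = cell_reaction_rates(
                y[0, i], y[1, i], y[2, i], p, cells_per_ml, config)
            flux[i] = config.quantum_yield * v * photon_factor
    else:
        v = y[1] * np.array([
            interpolate_velocity_oxygen(li, p, config, context)
            for li in y[0]])
        flux = config.quantum_yield * v * photon_factor
    flux = np.clip(flux, 0.0, None)

    hist = pd.DataFrame({"time_s": time_grid})
    for name, row in zip(labels, y):
        hist[name] = row
    hist["flux"] = flux
    trace = LuminescenceTrace(time_grid, flux, condition=context,
                              oxygen=oxygen, initial_substrate=l0)
    return BatchResult(trace=trace, history=hist)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def fit_exponential_decay(trace: LuminescenceTrace,
                          window: tuple[float, float] | None = None,
                          unit_scale: float = 1e-6) -> dict:
    """Least-squares fit of A*exp(-k t) on a trace window.

    The fit is ordinary least squares on log-flux, which is exact for
    noise-free single-exponential data.  ``rate`` is reported in the printed
    decay unit (``rate_per_s / unit_scale``); ``rate_per_s`` in s^-1.
    """
    sub = trace if window is None else trace.window(*window)
    if len(sub) < 4:
        raise ValueError("at least 4 points are required in the fit window")
    if np.any(sub.flux <= 0):
        raise ValueError("fit window contains non-positive flux values")
    t, y = sub.time, np.log(sub.flux)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    k = max(-slope, 0.0)
    return {"rate": k / unit_scale, "rate_per_s": k,
            "amplitude": float(np.exp(intercept)), "r_squared": float(r2)}


def _biexp_model(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _ols_exp(t, logy):
    slope, intercept = np.polyfit(t, logy, 1)
    return max(-slope, 0.0), math.exp(intercept)


def fit_biexponential(trace: LuminescenceTrace,
                      unit_scale: float = 1e-6,
                      degeneracy_ratio: float = 2.0,
                      n_peel: int = 3) -> dict:
    """Fit A1 exp(-k1 t) + A2 exp(-k2 t) with k1 > k2 to the post-peak trace.

    The fit proceeds by iterative curve peeling, the classical approach for
    well-separated rates: the slow component is fitted on the late window
    where the fast component has died out, subtracted, and the fast
    component fitted on the early positive remainder; windows are refined
    from the current estimates and the cycle repeated.  A global
    least-squares refinement of the two-exponential sum (log residuals) is
    adopted only when the sum model actually describes the whole trace;
    traces whose two phases join through a kinetic regime switch have a
    knee sharper than any two-exponential sum, and for those the peeled
    asymptotic rates are the faithful estimates.

    If the two rates differ by less than ``degeneracy_ratio`` the fit is
    declared degenerate: a mono-exponential is returned with
    ``rate_fast == rate_slow`` and a :class:`DegenerateFitWarning`.
    """
    import lmfit

    if len(trace) < 8:
        raise ValueError("at least 8 points are required for a bi-exponential fit")
    i_peak = int(np.argmax(trace.flux))
    t_all = trace.time[i_peak:] - trace.time[i_peak]
    y_all = trace.flux[i_peak:]
    keep = y_all > 0
    t_all, y_all = t_all[keep], y_all[keep]
    if len(t_all) < 8:
        raise ValueError("too few positive post-peak samples")
    logy = np.log(y_all)
    span = t_all[-1] - t_all[0]

    def mono_result():
        mono = fit_exponential_decay(
            LuminescenceTrace(t_all + trace.time[i_peak], y_all,
                              trace.condition, trace.oxygen,
                              trace.initial_substrate),
            unit_scale=unit_scale)
        k = mono["rate_per_s"]
        return {"rate_fast": mono["rate"], "rate_slow": mono["rate"],
                "rate_fast_per_s": k, "rate_slow_per_s": k,
                "amplitudes": (mono["amplitude"], 0.0),
                "split_time": math.inf, "degenerate": True}

    # fast branch: seed fit on the earliest decade, extended forward until
    # the trace departs upward from the extrapolated early exponential
    n = len(t_all)
    n_seed = max(5, n // 10)
    k1, a1 = _ols_exp(t_all[:n_seed], logy[:n_seed])
    seed_resid = logy[:n_seed] - (math.log(a1) - k1 * t_all[:n_seed])
    tol = max(0.03, 4.0 * float(np.std(seed_resid)))
    dev = logy - (math.log(a1) - k1 * t_all)
    beyond = np.flatnonzero(dev > tol)
    i_stop = int(beyond[0]) if beyond.size else n
    m_fast = np.zeros(n, dtype=bool)
    m_fast[:max(i_stop, 4)] = True
    k1, a1 = _ols_exp(t_all[m_fast], logy[m_fast])

    # slow branch: peel where the fitted fast component is extinct
    k2 = a2 = None
    for _ in range(n_peel):
        fast = a1 * np.exp(-np.minimum(k1 * t_all, 700.0))
        m_slow = fast < 0.02 * y_all
        if np.sum(m_slow) < 4:
            warnings.warn("bi-exponential fit is degenerate (no resolvable "
                          "slow component); returning mono-exponential",
                          DegenerateFitWarning)
            return mono_result()
        rem = y_all[m_slow] - fast[m_slow]
        k2, a2 = _ols_exp(t_all[m_slow], np.log(np.maximum(rem, 1e-300)))

    if k2 is None or k2 <= 0 or k1 <= 0 or k1 / max(k2, 1e-300) < degeneracy_ratio:
        warnings.warn("bi-exponential fit is degenerate (rate ratio < "
                      f"{degeneracy_ratio}); returning mono-exponential",
                      DegenerateFitWarning)
        return mono_result()

    # global refinement, adopted only if the sum model fits the whole trace
    params = lmfit.Parameters()
    params.add("k_slow", value=k2, min=1e-15)
    params.add("ratio", value=k1 / k2, min=1.0)
    params.add("k_fast", expr="k_slow * ratio")
    params.add("log_a1", value=math.log(a1))
    params.add("log_a2", value=math.log(a2))

    def resid(pars):
        model = _biexp_model(t_all, math.exp(pars["log_a1"].value),
                             pars["k_fast"].value,
                             math.exp(pars["log_a2"].value),
                             pars["k_slow"].value)
        return np.log(np.maximum(model, 1e-300)) - logy

    try:
        out = lmfit.minimize(resid, params, method="leastsq")
        r = resid(out.params)
        w = min(9, max(3, len(r) // 20) | 1)
        smooth = np.convolve(r, np.ones(w) / w, mode="valid")
        systematic = (np.max(np.abs(smooth)) > 0.05 and
                      np.max(np.abs(smooth)) >
                      4.0 * np.median(np.abs(smooth)) + 1e-12)
        if out.success and not systematic:
            k1 = out.params["k_fast"].value
            k2 = out.params["k_slow"].value
            a1 = math.exp(out.params["log_a1"].value)
            a2 = math.exp(out.params["log_a2"].value)
    except Exception:   # refinement is optional; peeled estimates stand
        pass

    if k1 / k2 < degeneracy_ratio:
        warnings.warn("bi-exponential fit is degenerate (rate ratio < "
                      f"{degeneracy_ratio}); returning mono-exponential",
                      DegenerateFitWarning)
        return mono_result()

    split = math.log(a1 / a2) / (k1 - k2) if a2 > 0 else math.inf
    return {"rate_fast": k1 / unit_scale, "rate_slow": k2 / unit_scale,
            "rate_fast_per_s": k1, "rate_slow_per_s": k2,
            "amplitudes": (a1, a2),
            "split_time": split + trace.time[i_peak],
            "degenerate": False}


def extrapolate_initial_velocity(trace: LuminescenceTrace,
                                 paired_hypoxic_trace: LuminescenceTrace | None = None,
                                 ratio_criterion: float = 3.37,
                                 unit_scale: float = 1e-6) -> dict:
    """Extrapolate a decaying activity trace to its initial time point.

    Fits an exponential decay; without a hypoxic pair the initial velocity
    is simply the fitted amplitude at t = 0.  With a pair, the initial time
    point t0 is solved (by bisection on the ratio of the two fitted
    exponentials) such that v0(normoxic)/v0(hypoxic) = ``ratio_criterion``,
    emulating the ratiometric criterion used to anchor dynamic time-point
    measurements against the glow-mode fold difference.
    """
    fit_n = fit_exponential_decay(trace, unit_scale=unit_scale)
    if paired_hypoxic_trace is None:
        return {"t0": 0.0, "v0": fit_n["amplitude"], "ratio": None,
                "fit": fit_n}
    fit_h = fit_exponential_decay(paired_hypoxic_trace,
                                  unit_scale=unit_scale)
    a_n, k_n = fit_n["amplitude"], fit_n["rate_per_s"]
    a_h, k_h = fit_h["amplitude"], fit_h["rate_per_s"]

    def log_ratio(t):
        return math.log(a_n / a_h) - (k_n - k_h) * t - math.log(ratio_criterion)

    t_hi = max(trace.time[-1], paired_hypoxic_trace.time[-1]) * 10.0
    lo, hi = log_ratio(0.0), log_ratio(t_hi)
    if lo == 0.0:
        t0 = 0.0
    elif lo * hi > 0:
        raise ValueError(
            "ratiometric criterion unattainable: fitted velocity ratio "
            f"spans [{math.exp(min(lo, hi) + math.log(ratio_criterion)):.3g}, "
            f"{math.exp(max(lo, hi) + math.log(ratio_criterion)):.3g}] "
            f"* {ratio_criterion:.3g} never crossing 1")
    else:
        t0 = brentq(log_ratio, 0.0, t_hi, xtol=1e-10, rtol=1e-14)
    v0_n = a_n * math.exp(-k_n * t0)
    v0_h = a_h * math.exp(-k_h * t0)
    return {"t0": t0, "v0": v0_n, "v0_pair": v0_h, "ratio": v0_n / v0_h,
            "fit": fit_n, "fit_pair": fit_h}


def lineweaver_burk(dataset: VelocityDataset) -> dict:
    """Double-reciprocal Michaelis-Menten fit.

    Ordinary least squares on (1/S, 1/v): Km = slope/intercept,
    Vmax = 1/intercept.  ``r_squared`` refers to the reciprocal-space line.
    Zero or negative velocities are excluded with a warning.
    """
    s, v = dataset.substrate_conc, dataset.velocity
    keep = v > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} non-positive velocities "
                      "from Lineweaver-Burk fit")
        s, v = s[keep], v[keep]
    if len(np.unique(s)) < 3:
        raise ValueError("at least 3 distinct positive-velocity points required")
    x, y = 1.0 / s, 1.0 / v
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        raise RuntimeError(
            "Lineweaver-Burk intercept is non-positive; data are not "
            "consistent with saturating Michaelis-Menten kinetics")
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return {"km": float(slope / intercept), "vmax": float(1.0 / intercept),
            "r_squared": float(r2),
            "line_params": (float(slope), float(intercept))}


def equivalent_cell_density(enzyme_nM: float = 0.1,
                            luciferase_per_cell_amol: float = 0.92) -> float:
    """Cell density (cells/ml) equivalent to a free-luciferase solution.

    Converts a molar enzyme concentration into the density of cells carrying
    the average intracellular luciferase content, e.g. 0.1 nM with
    0.92 amol/cell gives ~1.09e5 cells/ml.
    """
    if enzyme_nM < 0 or luciferase_per_cell_amol <= 0:
        raise ValueError("enzyme and per-cell content must be positive")
    # nM -> mol/ml: 1e-9 mol/L * 1e-3 L/ml; amol -> 1e-18 mol
    return enzyme_nM * 1e-12 / (luciferase_per_cell_amol * 1e-18)
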
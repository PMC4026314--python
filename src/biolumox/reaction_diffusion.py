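"""Axisymmetric reaction-diffusion model of a cell-seeded hydrogel.

The experimental geometry is a cylindrical agarose gel (default 8 mm
diameter, 2 mm height) confined axially between glass plates, so oxygen and
luciferin enter only through the lateral rim and the problem reduces to one
radial dimension.  Cells consume oxygen at a Michaelis-Menten rate
(per-cell maximal OCR, saturation constant ``k_o2``) and take up luciferin
across their membranes; the local bioluminescence kinetics are the
well-mixed intact-cell network of :mod:`biolumox.kinetics` evaluated with
the local oxygen level.  The surrounding medium is a finite well-mixed bath
exchanging luciferin with the gel rim, so luciferin is globally conserved
(bath + gel + emitted photons / quantum yield).

Discretisation is a conservative finite-volume scheme on a uniform radial
grid (annular control volumes, face-centred fluxes, zero flux at the
symmetry axis) integrated by a stiff method-of-lines solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .config import (AVOGADRO, NORMOXIC_PERCENT, BATH_LUCIFERIN_UM,
                     BATH_VOLUME_ML, D_LUCIFERIN_GEL, D_OXYGEN_GEL, CellField,
                     GelGeometry, KineticConfig, SolverOptions)
from .kinetics import (LuminescenceTrace, cell_reaction_rates,
                       fit_exponential_decay)

__all__ = [
    "SpatioTemporalState",
    "PeakSummary",
    "NoPeakError",
    "solve_oxygen_radial",
    "steady_oxygen_profile",
    "solve_coupled_bioluminescence",
    "peak_parameters",
    "estimate_ocr",
    "infer_oxygen_from_peaks",
    "render_topview_radiance",
]

#: photons/s emitted per (µM/s reaction rate x µm^3 volume)
_PHOTONS_PER_UM3_UM = 1e-21 * AVOGADRO


class NoPeakError(ValueError):
    """Raised when a trace has no interior emission peak."""


@dataclass(frozen=True)
class SpatioTemporalState:
    """Radial fields of the coupled gel simulation on a common grid."""

    grid: np.ndarray             # radial node centres, µm
    times: np.ndarray            # s
    o2: np.ndarray               # µM, shape (nt, nr)
    luciferin_ext: np.ndarray    # µM (gel pore space), (nt, nr)
    luciferin_int: np.ndarray    # µM per total volume, (nt, nr)
    enzyme: np.ndarray           # active fraction of initial, (nt, nr)
    flux: np.ndarray             # photons s^-1 per node, (nt, nr)
    bath_luciferin: np.ndarray | None = None   # µM, (nt,)
    cumulative_photons: np.ndarray | None = None  # µM µm^3 equivalents, (nt,)

    def __post_init__(self):
        nt, nr = len(self.times), len(self.grid)
        for name in ("o2", "luciferin_ext", "luciferin_int", "enzyme", "flux"):
            arr = getattr(self, name)
            if arr.shape != (nt, nr):
                raise ValueError(f"{name} must have shape (times, grid)")
            if np.any(arr < -1e-9):
                raise ValueError(f"{name} contains negative values")


@dataclass(frozen=True)
class PeakSummary:
    """Shape parameters of a bioluminescence emission peak."""

    t_peak: float        # s
    height: float        # flux units
    fwhm: float          # s
    decay_rate: float    # printed decay unit
    gauss_r2: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    def features(self) -> np.ndarray:
        return np.array([self.t_peak, self.fwhm, self.decay_rate])


# ---------------------------------------------------------------------------
# finite-volume helpers
# ---------------------------------------------------------------------------

def _fv_grid(radius_um: float, n_r: int):
    """Cell-centred radial grid with face radii and annulus areas.

    Returns (centres, dr, face_radii, cell_area_weights) where the area
    weights are per unit height: pi*(rf[i+1]^2 - rf[i]^2).
    """
    dr = radius_um / n_r
    faces = np.linspace(0.0, radius_um, n_r + 1)
    centres = 0.5 * (faces[:-1] + faces[1:])
    areas = math.pi * (faces[1:] ** 2 - faces[:-1] ** 2)
    return centres, dr, faces, areas


def _diffusion_op(conc, boundary_value, d, dr, faces, areas):
    """Conservative radial diffusion rate of change, Dirichlet at the rim.

    Returns (dc_dt, rim_flux) with rim_flux the amount (conc x area/height)
    entering through the outer face per unit time per unit height, positive
    into the gel.
    """
    n = len(conc)
    # interior face fluxes: F = -D dC/dr * 2*pi*r_face (per unit height)
    grad = np.diff(conc) / dr
    face_flux = d * grad * 2.0 * math.pi * faces[1:-1]  # positive inward i+1->i
    rim_flux = d * (boundary_value - conc[-1]) / (0.5 * dr) * 2.0 * math.pi * faces[-1]
    dc = np.zeros(n)
    dc[0] = face_flux[0]
    if n > 1:
        dc[1:-1] = face_flux[1:] - face_flux[:-1]
        dc[-1] = rim_flux - face_flux[-1]
    else:
        dc[0] = rim_flux
    return dc / areas, rim_flux


# ---------------------------------------------------------------------------
# oxygen transport
# ---------------------------------------------------------------------------

def solve_oxygen_radial(geometry: GelGeometry, cells: CellField,
                        d_oxygen: float = D_OXYGEN_GEL,
                        boundary_o2: float = 200.0,
                        t_span: float = 86400.0,
                        n_r: int = 101, n_t: int = 60,
                        day: int = 1, initial_o2: float | None = None,
                        solver: SolverOptions | None = None):
    """Oxygen diffusion-consumption in the confined gel.

    Solves dO/dt = D (1/r) d/dr(r dO/dr) - rho*viability*OCR(t)*O/(k+O)
    with symmetry at r = 0 and a Dirichlet rim held at ``boundary_o2``.
    Returns ``(r_um, times, o2)`` with o2 of shape (n_t, n_r).
    """
    if d_oxygen <= 0:
        raise ValueError("diffusivity must be positive")
    if boundary_o2 < 0:
        raise ValueError("boundary oxygen must be non-negative")
    if n_r < 20:
        raise ValueError("grid too coarse: at least 20 radial nodes required")
    solver = solver or SolverOptions()
    r, dr, faces, areas = _fv_grid(geometry.radius_um, n_r)
    viab = cells.viability(r)
    # per-cell amol/s at density cells/ml -> µM/s (factor 1e-3 per 1e6/ml)
    q_max = cells.density_per_ml / 1e6 * cells.ocr(day) * 1e-3 * viab
    k = cells.k_o2
    o0 = boundary_o2 if initial_o2 is None else initial_o2

    def rhs(t, o):
        oc = np.maximum(o, 0.0)
        diff, _ = _diffusion_op(oc, boundary_o2, d_oxygen, dr, faces, areas)
        return diff - q_max * oc / (k + oc)

    times = np.linspace(0.0, t_span, n_t)
    sol = solve_ivp(rhs, (0.0, t_span), np.full(n_r, o0), method="LSODA",
                    t_eval=times, rtol=solver.rtol, atol=solver.atol)
    if not sol.success:
        raise RuntimeError(f"oxygen solver failed: {sol.message}")
    return r, times, np.clip(sol.y.T, 0.0, None)


def steady_oxygen_profile(geometry: GelGeometry, cells: CellField,
                          d_oxygen: float = D_OXYGEN_GEL,
                          boundary_o2: float = 200.0,
                          n_r: int = 101, day: int = 1,
                          ocr_override: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state radial oxygen profile (long-time limit of the PDE).

    Integrates the transient solver until the profile stops changing; the
    diffusion time R^2/D (~2 h at defaults) sets the horizon.
    """
    if ocr_override is not None:
        cells = CellField(density_per_ml=cells.density_per_ml,
                          ocr_per_day=(ocr_override,),
                          k_o2=cells.k_o2,
                          viability_profile=cells.viability_profile)
        day = 1
    t_diff = geometry.radius_um ** 2 / d_oxygen
    r, _, o2 = solve_oxygen_radial(geometry, cells, d_oxygen, boundary_o2,
                                   t_span=8.0 * t_diff, n_r=n_r, n_t=5,
                                   day=day)
    if np.max(np.abs(o2[-1] - o2[-2])) > 1e-6 * max(boundary_o2, 1.0):
        warnings.warn("steady-state not fully converged; increase t_span")
    return r, o2[-1]


# ---------------------------------------------------------------------------
# coupled bioluminescence
# ---------------------------------------------------------------------------

def solve_coupled_bioluminescence(geometry: GelGeometry, cells: CellField,
                                  config: KineticConfig,
                                  d_luciferin: float = D_LUCIFERIN_GEL,
                                  boundary_luciferin: float = BATH_LUCIFERIN_UM,
                                  t_span: float = 43200.0,
                                  d_oxygen: float = D_OXYGEN_GEL,
                                  boundary_o2: float = 200.0,
                                  bath_volume_ml: float = BATH_VOLUME_ML,
                                  respiration: bool = True,
                                  pre_equilibrated_luciferin: bool = False,
                                  day: int = 1,
                                  n_r: int = 101, n_t: int = 120,
                                  initial_o2: float | None = None,
                                  solver: SolverOptions | None = None):
    """Co-integrate oxygen, luciferin transport/uptake and photon emission.

    The gel exchanges luciferin with a finite well-mixed bath (volume
    ``bath_volume_ml`` at initial concentration ``boundary_luciferin``);
    oxygen is held at ``boundary_o2`` on the rim (the incubated medium is
    continuously re-aerated).  With ``respiration=False`` the oxygen field
    is pinned uniform at the boundary value, isolating the
    oxygen-independent signal.  ``pre_equilibrated_luciferin`` starts the
    gel pore space already at the bath concentration (overnight soak)
    instead of luciferin-free.

    Returns ``(state, trace)``: the full :class:`SpatioTemporalState` and
    the gel-total photon-flux trace.
    """
    if n_r < 20:
        raise ValueError("grid too coarse: at least 20 radial nodes required")
    solver = solver or SolverOptions()
    r, dr, faces, areas = _fv_grid(geometry.radius_um, n_r)
    height = geometry.height_um
    vol_nodes = areas * height                      # µm^3 per node
    bath_um3 = bath_volume_ml * 1e12
    viab = cells.viability(r)
    dens_eff = cells.density_per_ml * viab          # cells/ml per node
    e0 = config.enzyme_um_per_cell_density(np.maximum(dens_eff, 1e-300))
    q_max = dens_eff / 1e6 * cells.ocr(day) * 1e-3
    k_o2 = cells.k_o2
    p_to_percent = NORMOXIC_PERCENT / config.c_sat

    n = n_r
    o_sl = slice(0, n)
    lx_sl = slice(n, 2 * n)
    li_sl = slice(2 * n, 3 * n)
    e_sl = slice(3 * n, 4 * n)
    i_bath = 4 * n
    i_phot = 4 * n + 1

    act = dens_eff > 0

    def node_kinetics(lx, li, e, o2):
        j = np.zeros(n)
        v = np.zeros(n)
        kd = np.zeros(n)
        if np.any(act):
            p_loc = np.clip(o2[act] * p_to_percent, 0.0, NORMOXIC_PERCENT)
            j[act], v[act], kd[act], _ = cell_reaction_rates(
                lx[act], li[act], e[act], p_loc, dens_eff[act], config)
        return j, v, kd

    def rhs(t, y):
        o2 = np.maximum(y[o_sl], 0.0)
        lx = np.maximum(y[lx_sl], 0.0)
        li = np.maximum(y[li_sl], 0.0)
        e = np.maximum(y[e_sl], 0.0)
        bath = max(y[i_bath], 0.0)
        dy = np.zeros_like(y)
        if respiration:
            diff_o, _ = _diffusion_op(o2, boundary_o2, d_oxygen, dr, faces,
                                      areas)
            dy[o_sl] = diff_o - q_max * o2 / (k_o2 + o2)
        diff_l, rim = _diffusion_op(lx, bath, d_luciferin, dr, faces, areas)
        j, v, kd = node_kinetics(lx, li, e, o2)
        dy[lx_sl] = diff_l - j
        dy[li_sl] = j - v
        dy[e_sl] = -kd * e
        dy[i_bath] = -rim * height / bath_um3
        dy[i_phot] = config.quantum_yield * float(np.dot(v, vol_nodes))
        return dy

    y0 = np.zeros(4 * n + 2)
    y0[o_sl] = boundary_o2 if initial_o2 is None else initial_o2
    y0[lx_sl] = boundary_luciferin if pre_equilibrated_luciferin else 0.0
    y0[e_sl] = e0
    y0[i_bath] = boundary_luciferin

    times = np.linspace(0.0, t_span, n_t)
    sol = solve_ivp(rhs, (0.0, t_span), y0, method="LSODA", t_eval=times,
                    rtol=solver.rtol, atol=solver.atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"coupled gel solver failed: {sol.message}")

    y = sol.y
    o2 = np.clip(y[o_sl, :].T, 0.0, None)
    lx = np.clip(y[lx_sl, :].T, 0.0, None)
    li = np.clip(y[li_sl, :].T, 0.0, None)
    en = np.clip(y[e_sl, :].T, 0.0, None)
    bath = np.clip(y[i_bath, :], 0.0, None)

    flux = np.zeros((n_t, n))
    for it in range(n_t):
        _, v, _ = node_kinetics(lx[it], li[it], en[it], o2[it])
        flux[it] = (config.quantum_yield * v * vol_nodes
                    * _PHOTONS_PER_UM3_UM)
    e_frac = en / np.maximum(e0, 1e-300)

    state = SpatioTemporalState(grid=r, times=times, o2=o2,
                                luciferin_ext=lx, luciferin_int=li,
                                enzyme=e_frac, flux=flux,
                                bath_luciferin=bath,
                                cumulative_photons=np.clip(y[i_phot, :], 0.0,
                                                           None))
    total = flux.sum(axis=1)
    trace = LuminescenceTrace(times[1:], total[1:], condition="gel-average",
                              oxygen=None,
                              initial_substrate=boundary_luciferin)
    return state, trace


def luciferin_inventory(state: SpatioTemporalState, geometry: GelGeometry,
                        config: KineticConfig, bath_volume_ml: float,
                        photons_um: np.ndarray | None = None) -> np.ndarray:
    """Total luciferin-equivalents (µmol-scale internal units) per frame.

    bath + gel(ext + int); add consumed = photons/quantum_yield separately
    when provided to verify conservation.
    """
    r = state.grid
    n = len(r)
    dr = geometry.radius_um / n
    faces = np.linspace(0.0, geometry.radius_um, n + 1)
    vol = math.pi * (faces[1:] ** 2 - faces[:-1] ** 2) * geometry.height_um
    gel = (state.luciferin_ext + state.luciferin_int) @ vol
    bath = state.bath_luciferin * bath_volume_ml * 1e12
    total = gel + bath
    if photons_um is None:
        photons_um = state.cumulative_photons
    if photons_um is not None:
        total = total + photons_um / config.quantum_yield
    return total


# ---------------------------------------------------------------------------
# peak analysis
# ---------------------------------------------------------------------------

def peak_parameters(trace: LuminescenceTrace,
                    unit_scale: float = 1e-6) -> PeakSummary:
    """Gaussian peak fit plus tail decay rate of an emission trace.

    The Gaussian is fitted to the contiguous region above half maximum
    around the interior peak (FWHM = 2 sqrt(2 ln 2) sigma); the decay rate
    comes from an exponential fit of the tail beyond twice the peak time.
    """
    import lmfit

    t, y = trace.time, trace.flux
    i_pk = int(np.argmax(y))
    if i_pk == 0 or i_pk == len(y) - 1:
        raise NoPeakError("trace has no interior maximum")
    half = y[i_pk] / 2.0
    lo = i_pk
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = i_pk
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    if hi - lo + 1 < 4:
        lo, hi = max(0, i_pk - 3), min(len(y) - 1, i_pk + 3)
    ts, ys = t[lo:hi + 1], y[lo:hi + 1]

    model = lmfit.models.GaussianModel()
    sigma0 = max((ts[-1] - ts[0]) / 2.355, (t[1] - t[0]))
    pars = model.make_params(center=t[i_pk], sigma=sigma0,
                             amplitude=y[i_pk] * sigma0 * math.sqrt(2 * math.pi))
    out = model.fit(ys, pars, x=ts)
    sigma = out.params["sigma"].value
    center = out.params["center"].value
    height = out.params["height"].value
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(out.residual ** 2)) / ss_tot if ss_tot > 0 else 1.0

    tail = trace.window(t_min=2.0 * max(center, t[i_pk]))
    if len(tail) >= 4 and np.all(tail.flux > 0):
        decay = fit_exponential_decay(tail, unit_scale=unit_scale)["rate"]
    else:
        decay = math.nan
    return PeakSummary(t_peak=float(center), height=float(height),
                       fwhm=float(2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma),
                       decay_rate=float(decay), gauss_r2=float(r2))


# ---------------------------------------------------------------------------
# OCR estimation and oxygen inversion
# ---------------------------------------------------------------------------

def estimate_ocr(profiles, geometry: GelGeometry, d_oxygen: float = D_OXYGEN_GEL,
                 cells: CellField | None = None, boundary_o2: float = 200.0,
                 n_r: int = 61) -> list[dict]:
    """Fit per-day cell OCR values to measured radial oxygen profiles.

    ``profiles`` is a list (one entry per day) of ``(r_um, o2_um)`` arrays
    with at least 3 radial positions each.  Each day's steady model profile
    is matched to the data by least squares over a single per-cell OCR.
    Returns one dict per day with ``ocr`` (amol/cell/s), ``residual`` and
    the fitted profile.
    """
    cells = cells or CellField()
    results = []
    for day_idx, (r_obs, o_obs) in enumerate(profiles, start=1):
        r_obs = np.asarray(r_obs, dtype=float)
        o_obs = np.asarray(o_obs, dtype=float)
        if len(r_obs) < 3:
            raise ValueError("at least 3 radial positions per profile required")

        def model(log_ocr):
            r_m, o_m = steady_oxygen_profile(
                geometry, cells, d_oxygen, boundary_o2, n_r=n_r,
                ocr_override=float(np.exp(log_ocr)))
            return np.interp(r_obs, r_m, o_m)

        def resid(p):
            return model(p[0]) - o_obs

        # initial guess from the parabolic (zero-order) depth of the profile
        depth = max(boundary_o2 - float(np.min(o_obs)), 1e-3)
        q0 = 4.0 * d_oxygen * depth / geometry.radius_um ** 2   # µM/s
        ocr0 = max(q0 / max(cells.density_per_ml / 1e6 * 1e-3, 1e-12), 1e-3)
        out = least_squares(resid, [np.log(ocr0)], method="lm", xtol=1e-12)
        if not out.success:
            raise RuntimeError(
                f"OCR fit failed for day {day_idx}: residual norm "
                f"{np.linalg.norm(out.fun):.3g}")
        ocr = float(np.exp(out.x[0]))
        results.append({"day": day_idx, "ocr": ocr,
                        "residual": float(np.linalg.norm(out.fun)),
                        "fitted": model(out.x[0])})
    return results


def infer_oxygen_from_peaks(summary: PeakSummary,
                            library: list[tuple[float, PeakSummary]]) -> dict:
    """Invert peak parameters to a mean oxygen estimate via a library.

    The library maps mean O2 levels to simulated :class:`PeakSummary`
    entries.  Features (t_peak, fwhm, decay_rate) are normalised by the
    library spread; the query is projected onto the segment joining the
    nearest entry and its best neighbour (local linear interpolation).
    Queries outside the library hull raise.
    """
    if not library:
        raise ValueError("peak-parameter library is empty")
    lib = sorted(library, key=lambda e: e[0])
    o2s = np.array([e[0] for e in lib])
    feats = np.stack([e[1].features() for e in lib])
    scale = np.std(feats, axis=0)
    scale[scale == 0] = 1.0
    fq = summary.features() / scale
    fl = feats / scale
    d = np.linalg.norm(fl - fq, axis=1)
    i = int(np.argmin(d))
    if d[i] < 1e-12:
        return {"o2": float(o2s[i]), "bracket": (float(o2s[i]), float(o2s[i])),
                "distance": 0.0}
    # candidate segments adjacent to the nearest entry, low index -> high
    best = None
    for a, b in ((i - 1, i), (i, i + 1)):
        if a < 0 or b >= len(lib):
            continue
        seg = fl[b] - fl[a]
        l2 = float(seg @ seg)
        if l2 == 0:
            continue
        s = float((fq - fl[a]) @ seg) / l2
        resid = float(np.linalg.norm(fl[a] + np.clip(s, 0, 1) * seg - fq))
        if best is None or resid < best[0]:
            best = (resid, a, b, s)
    if best is None:
        raise ValueError("library must contain at least 2 entries for interpolation")
    _, a, b, s = best
    if (s < -0.05 and a == 0) or (s > 1.05 and b == len(lib) - 1):
        raise ValueError(
            "query lies outside the library hull; extend the simulated "
            "oxygen span before inverting")
    s = float(np.clip(s, 0.0, 1.0))
    o2 = float(o2s[a] + s * (o2s[b] - o2s[a]))
    return {"o2": o2, "bracket": (float(o2s[a]), float(o2s[b])),
            "distance": float(d[i])}


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def render_topview_radiance(state: SpatioTemporalState, geometry: GelGeometry,
                            pixel_size_mm: float = 0.025,
                            time_index: int | None = None,
                            per_steradian: bool = False) -> np.ndarray:
    """Project the axisymmetric flux field to a top-view disk image.

    Per-pixel value is the local photon emission per unit area (the axial
    column is uniform under confinement): photons s^-1 cm^-2, divided by
    4 pi when ``per_steradian`` (isotropic emission).  Returns an array of
    shape (n_pix, n_pix) or (n_t, n_pix, n_pix) when ``time_index`` is
    None.
    """
    if pixel_size_mm <= 0 or pixel_size_mm * 1e3 > geometry.radius_um:
        raise ValueError("pixel size must be positive and smaller than the radius")
    r = state.grid
    n = len(r)
    dr = geometry.radius_um / n
    faces = np.linspace(0.0, geometry.radius_um, n + 1)
    area_cm2 = math.pi * (faces[1:] ** 2 - faces[:-1] ** 2) * 1e-8
    pix_um = pixel_size_mm * 1e3
    half = geometry.radius_um
    n_pix = int(math.ceil(2.0 * half / pix_um))
    ax = (np.arange(n_pix) + 0.5) * pix_um - half
    xx, yy = np.meshgrid(ax, ax)
    rr = np.hypot(xx, yy)
    inside = rr <= geometry.radius_um

    def render_one(it):
        dens = state.flux[it] / area_cm2          # photons s^-1 cm^-2
        img = np.zeros((n_pix, n_pix))
        img[inside] = np.interp(rr[inside], r, dens,
                                left=dens[0], right=dens[-1])
        if per_steradian:
            img /= 4.0 * math.pi
        return img

    if time_index is not None:
        return render_one(time_index)
    return np.stack([render_one(it) for it in range(len(state.times))])
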
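"""Configuration records for the bioluminescence-oxygen model.

All rate, affinity, transport and geometry parameters live in small frozen
dataclasses that validate themselves on construction.  Concentrations are in
µM, lengths in µm unless a field name says otherwise, times in seconds.

Enzyme-decay constants are a special case: the literature values for firefly
luciferase inactivation under the assay conditions modelled here are quoted
in a nominal "s^-1" unit whose absolute scale is ambiguous (taken literally
they would extinguish a glow reaction in milliseconds).  They are therefore
stored verbatim in that printed unit and converted internally through
``decay_unit_scale`` (s^-1 per printed unit), whose default of 1e-6 places
the decay times on the minute-to-hour scale of glow kinetics.  Every fitting
routine reports rates in both the printed unit and s^-1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "ConfigError",
    "OxygenLevel",
    "normoxia",
    "hypoxia",
    "KineticConfig",
    "GelGeometry",
    "CellField",
    "SolverOptions",
    "PipelineConfig",
    "AVOGADRO",
    "NORMOXIC_PERCENT",
]

AVOGADRO = 6.02214076e23
#: atmospheric oxygen fraction used as the normoxic reference, in percent
NORMOXIC_PERCENT = 21.0


class ConfigError(ValueError):
    """Raised when a configuration record violates its invariants.

    ``messages`` collects one named message per offending field so that a
    single load reports every problem at once.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def _check(cond: bool, msg: str, bag: list[str]) -> None:
    if not cond:
        bag.append(msg)


@dataclass(frozen=True)
class OxygenLevel:
    """Oxygen availability expressed both as % of atmosphere and dissolved µM.

    ``dissolved`` is tied to ``percent`` through the saturation concentration
    ``c_sat`` (dissolved O2 at 21 %): dissolved = percent * c_sat / 21.
    """

    percent: float
    dissolved: float

    def __post_init__(self):
        bag: list[str] = []
        _check(0.0 <= self.percent <= NORMOXIC_PERCENT,
               f"percent: must lie in [0, 21], got {self.percent}", bag)
        _check(self.dissolved >= 0.0,
               f"dissolved: must be non-negative, got {self.dissolved}", bag)
        if bag:
            raise ConfigError(bag)

    @classmethod
    def from_percent(cls, percent: float, c_sat: float = 200.0) -> "OxygenLevel":
        return cls(percent=float(percent),
                   dissolved=float(percent) * c_sat / NORMOXIC_PERCENT)

    @property
    def is_normoxic(self) -> bool:
        return math.isclose(self.percent, NORMOXIC_PERCENT, abs_tol=1e-9)

    @property
    def is_hypoxic(self) -> bool:
        return math.isclose(self.percent, 0.0, abs_tol=1e-9)


def normoxia(c_sat: float = 200.0) -> OxygenLevel:
    """21 % O2, the atmospheric reference condition."""
    return OxygenLevel.from_percent(NORMOXIC_PERCENT, c_sat)


def hypoxia(c_sat: float = 200.0) -> OxygenLevel:
    """~0 % O2 (sulfite-scavenged in the experiments being emulated)."""
    return OxygenLevel.from_percent(0.0, c_sat)


@dataclass(frozen=True)
class KineticConfig:
    """Rate/affinity/decay/transport parameters of the bioluminescence model.

    Michaelis constants and the intact-cell crowding factor come from
    double-reciprocal fits of initial-velocity data at the two oxygen
    endpoints; decay constants are per-condition first-order enzyme
    inactivation rates in the printed unit (see module docstring).  Membrane
    transport is a lumped permeability acting on the luciferin concentration
    step across the cell membrane with an equilibrium partition coefficient.
    """

    # Michaelis-Menten
    v_max: float = 1.6              # photons s^-1 per enzyme (turnover kcat)
    km_normoxic: float = 42.6       # µM, lysate/free enzyme at 21 % O2
    km_hypoxic: float = 938.4       # µM, lysate/free enzyme at ~0 % O2
    km_cell_factor: float = 1.5     # crowded-cytoplasm multiplier, intact cells
    # enzyme decay, printed unit (x decay_unit_scale -> s^-1)
    decay_lysate_normoxic: float = 3948.0
    decay_lysate_hypoxic: float = 1452.0
    decay_cell_fast_normoxic: float = 180.0
    decay_cell_slow_normoxic: float = 27.0
    decay_cell_hypoxic: float = 3.0
    decay_unit_scale: float = 1e-6  # s^-1 per printed decay unit
    # regime switch on intracellular luciferin
    kappa: float = 400.0            # µM intracellular luciferin threshold
    kappa_blend_width: float = 0.01  # logistic blend width, fraction of kappa
    # membrane transport
    permeability: float = 0.3       # µm s^-1
    membrane_thickness: float = 0.008  # µm (lambda_c)
    partition_coeff: float = 1.0    # equilibrium intra/extra luciferin ratio
    cell_diameter: float = 15.0     # µm, spherical-equivalent 293T cell
    # enzyme content and assay criteria
    luciferase_per_cell: float = 0.92   # amol cell^-1
    velocity_ratio_criterion: float = 3.37  # normoxic/hypoxic v0 ratio
    # oxygen solubility and photon yield
    c_sat: float = 200.0            # µM dissolved O2 at 21 %
    quantum_yield: float = 0.41     # photons per luciferin oxidised

    def __post_init__(self):
        bag: list[str] = []
        positive = [
            "v_max", "km_normoxic", "km_hypoxic", "decay_lysate_normoxic",
            "decay_lysate_hypoxic", "decay_cell_fast_normoxic",
            "decay_cell_slow_normoxic", "decay_cell_hypoxic",
            "decay_unit_scale", "permeability", "membrane_thickness",
            "partition_coeff", "cell_diameter", "luciferase_per_cell",
            "velocity_ratio_criterion", "c_sat",
        ]
        for name in positive:
            _check(getattr(self, name) > 0.0,
                   f"{name}: must be strictly positive", bag)
        _check(self.kappa >= 0.0, "kappa: must be non-negative", bag)
        _check(self.kappa_blend_width > 0.0,
               "kappa_blend_width: must be strictly positive", bag)
        _check(self.km_hypoxic > self.km_normoxic,
               "km_hypoxic: must exceed km_normoxic "
               f"({self.km_hypoxic} <= {self.km_normoxic})", bag)
        _check(self.km_cell_factor >= 1.0,
               "km_cell_factor: must be >= 1", bag)
        _check(0.0 < self.quantum_yield <= 1.0,
               "quantum_yield: must lie in (0, 1]", bag)
        if bag:
            raise ConfigError(bag)

    # -- derived geometry ---------------------------------------------------
    @property
    def cell_volume(self) -> float:
        """Cell volume in µm^3."""
        return math.pi / 6.0 * self.cell_diameter ** 3

    @property
    def cell_area(self) -> float:
        """Cell membrane area in µm^2."""
        return math.pi * self.cell_diameter ** 2

    def km(self, oxygen: OxygenLevel, context: str = "lysate") -> float:
        """Endpoint Michaelis constant (µM) for the given oxygen/context."""
        if oxygen.is_normoxic:
            base = self.km_normoxic
        elif oxygen.is_hypoxic:
            base = self.km_hypoxic
        else:
            raise ValueError(
                "km is defined at the oxygen endpoints (0 or 21 %); use the "
                "square-root velocity interpolation for intermediate levels")
        if context == "cell":
            base *= self.km_cell_factor
        elif context not in ("lysate", "solution"):
            raise ValueError(f"unknown context {context!r}")
        return base

    def enzyme_um_per_cell_density(self, cells_per_ml: float) -> float:
        """Total-volume luciferase concentration (µM) at a cell density."""
        # amol cell^-1 * cells ml^-1 -> 1e-18 mol / 1e-3 L -> µM factor 1e-9
        return cells_per_ml * self.luciferase_per_cell * 1e-9

    def oxygen(self, percent: float) -> OxygenLevel:
        return OxygenLevel.from_percent(percent, self.c_sat)


@dataclass(frozen=True)
class GelGeometry:
    """Axially confined cylindrical hydrogel (axisymmetric, 1D radial)."""

    radius_mm: float = 4.0
    height_mm: float = 2.0
    axial_flux: str = "closed"   # glass plates block axial diffusion

    def __post_init__(self):
        bag: list[str] = []
        _check(self.radius_mm > 0, "radius_mm: must be positive", bag)
        _check(self.height_mm > 0, "height_mm: must be positive", bag)
        _check(self.axial_flux == "closed",
               "axial_flux: only 'closed' (glass-confined) is modelled", bag)
        if bag:
            raise ConfigError(bag)

    @property
    def radius_um(self) -> float:
        return self.radius_mm * 1e3

    @property
    def height_um(self) -> float:
        return self.height_mm * 1e3

    @property
    def volume_ml(self) -> float:
        return math.pi * self.radius_mm ** 2 * self.height_mm * 1e-3


@dataclass(frozen=True)
class CellField:
    """Cell seeding and respiration parameters of the hydrogel.

    ``ocr_per_day`` is the maximal per-cell oxygen consumption rate for each
    culture day (amol cell^-1 s^-1); respiration follows Michaelis-Menten
    saturation in local O2 with constant ``k_o2``.  ``viability_profile`` is
    an optional radial multiplier in [0, 1] (uniform when None).
    """

    density_per_ml: float = 1.0e6
    ocr_per_day: tuple[float, ...] = (60.0, 40.0, 25.0)
    k_o2: float = 10.0           # µM
    viability_profile: Callable[[float], float] | None = None

    def __post_init__(self):
        bag: list[str] = []
        _check(self.density_per_ml >= 0, "density_per_ml: must be >= 0", bag)
        _check(all(v >= 0 for v in self.ocr_per_day),
               "ocr_per_day: all values must be >= 0", bag)
        _check(self.k_o2 > 0, "k_o2: must be positive", bag)
        if bag:
            raise ConfigError(bag)

    def ocr(self, day: int) -> float:
        """Per-cell maximal OCR (amol s^-1) on a 1-based culture day."""
        if not self.ocr_per_day:
            return 0.0
        idx = min(max(int(day), 1), len(self.ocr_per_day)) - 1
        return self.ocr_per_day[idx]

    def viability(self, r_um):
        if self.viability_profile is None:
            import numpy as np
            return np.ones_like(np.asarray(r_um, dtype=float))
        import numpy as np
        return np.asarray([self.viability_profile(float(r)) for r in
                           np.atleast_1d(r_um)], dtype=float)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical tolerances and grid sizes shared by the integrators."""

    rtol: float = 1e-8
    atol: float = 1e-12
    n_radial: int = 101

    def __post_init__(self):
        bag: list[str] = []
        _check(self.rtol > 0, "rtol: must be positive", bag)
        _check(self.atol > 0, "atol: must be positive", bag)
        _check(self.n_radial >= 20,
               "n_radial: at least 20 nodes are required to resolve the "
               "boundary layer", bag)
        if bag:
            raise ConfigError(bag)


# transport defaults for the gel problem (µm^2 s^-1); luciferin uses the
# agarose tracer value (fluorescein and beetle luciferin have near-identical
# molecular weight), oxygen the small-solute gel value.
D_LUCIFERIN_GEL = 350.0
D_OXYGEN_GEL = 2000.0
BATH_VOLUME_ML = 2.0
BATH_LUCIFERIN_UM = 47.0
#: reference diffusivity of Rhodamine 6G in water used for FCS calibration
D_RHODAMINE6G_WATER = 372.0
#: FCS-measured tracer diffusivity in 2 % agarose
D_FCS_AGAROSE = 338.0


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration namespace consumed by the CLI pipeline."""

    kinetic: KineticConfig = field(default_factory=KineticConfig)
    geometry: GelGeometry = field(default_factory=GelGeometry)
    cells: CellField = field(default_factory=CellField)
    solver: SolverOptions = field(default_factory=SolverOptions)
    d_luciferin: float = D_LUCIFERIN_GEL
    d_oxygen: float = D_OXYGEN_GEL
    bath_volume_ml: float = BATH_VOLUME_ML
    bath_luciferin_um: float = BATH_LUCIFERIN_UM
    seed: int = 0
    output_dir: str = "biolumox-out"

    def __post_init__(self):
        bag: list[str] = []
        _check(self.d_luciferin > 0, "d_luciferin: must be positive", bag)
        _check(self.d_oxygen > 0, "d_oxygen: must be positive", bag)
        _check(self.bath_volume_ml > 0, "bath_volume_ml: must be positive", bag)
        _check(self.bath_luciferin_um >= 0,
               "bath_luciferin_um: must be >= 0", bag)
        _check(int(self.seed) == self.seed and self.seed >= 0,
               "seed: must be a non-negative integer", bag)
        if bag:
            raise ConfigError(bag)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {
            "kinetic": plain(self.kinetic),
            "geometry": plain(self.geometry),
            "cells": {k: v for k, v in plain(self.cells).items()
                      if k != "viability_profile"},
            "solver": plain(self.solver),
            "d_luciferin": self.d_luciferin,
            "d_oxygen": self.d_oxygen,
            "bath_volume_ml": self.bath_volume_ml,
            "bath_luciferin_um": self.bath_luciferin_um,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        errors: list[str] = []
        parts: dict = {}
        for key, typ in (("kinetic", KineticConfig),
                         ("geometry", GelGeometry),
                         ("cells", CellField),
                         ("solver", SolverOptions)):
            sub = data.pop(key, {}) or {}
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                errors.append(f"{key}: unknown fields {sorted(unknown)}")
                sub = {k: v for k, v in sub.items() if k in known}
            if typ is CellField and "ocr_per_day" in sub:
                sub["ocr_per_day"] = tuple(sub["ocr_per_day"])
            try:
                parts[key] = typ(**sub)
            except ConfigError as err:
                errors.extend(f"{key}.{m}" for m in err.messages)
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known_top
        if unknown:
            errors.append(f"unknown fields {sorted(unknown)}")
            data = {k: v for k, v in data.items() if k in known_top}
        try:
            cfg = cls(**parts, **data)
        except ConfigError as err:
            errors.extend(err.messages)
            cfg = None
        if errors:
            raise ConfigError(errors)
        return cfg
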
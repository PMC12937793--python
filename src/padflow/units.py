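"""Physical units, vessel description and the hemodynamic-electrical R/L/C mapping.

The electrical analogy used throughout the package maps pressure to voltage
and volumetric flow to current.  A straight elastic vessel segment of length
``l``, inner radius ``r``, wall thickness ``h`` and Young's modulus ``E``
carrying a Newtonian fluid (viscosity ``mu``, density ``rho``) is lumped into
three elements:

* hydraulic resistance  R = 8 mu l / (pi r^4)     [Pa s m^-3]  (Poiseuille)
* inertance             L = rho l / (pi r^2)      [kg m^-4]
* volume compliance     C = 3 pi r^3 l / (2 E h)  [m^3 Pa^-1]  (thin wall)

All internal computation is SI (Pa, m, s, m^3/s).  mmHg and mL/s are accepted
at the interface and converted on entry/exit with 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = [
    "MMHG_PA",
    "ML_PER_S",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "VesselSegment",
    "AnalogRLC",
    "vessel_resistance",
    "vessel_inertance",
    "vessel_compliance",
    "vessel_to_rlc",
    "vessel_from_config",
]

#: Conversion constant, pascal per millimetre of mercury.
MMHG_PA = 133.322

#: Conversion constant, m^3/s per mL/s.
ML_PER_S = 1e-6


def mmhg_to_pa(p: float) -> float:
    """Convert a pressure from mmHg to Pa (exact linear, 133.322 Pa/mmHg)."""
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p / MMHG_PA


@dataclass(frozen=True)
class VesselSegment:
    """Physical description of a straight arterial segment.

    Parameters
    ----------
    length_l : float
        Segment length in metres.
    radius_r0 : float
        Inner (lumen) radius in metres.
    wall_thickness_h : float
        Wall thickness in metres; must be smaller than the radius.
    youngs_E : float
        Young's modulus of the wall in pascals.
    density_rho : float
        Fluid density in kg/m^3 (blood ~1060).
    viscosity_mu : float
        Dynamic viscosity in Pa.s (blood ~3.5e-3).
    """

    length_l: float
    radius_r0: float
    wall_thickness_h: float
    youngs_E: float
    density_rho: float
    viscosity_mu: float

    def __post_init__(self) -> None:
        for name in (
            "length_l",
            "radius_r0",
            "wall_thickness_h",
            "youngs_E",
            "density_rho",
            "viscosity_mu",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")
        if self.wall_thickness_h >= self.radius_r0:
            raise ValueError(
                "wall_thickness_h must be smaller than radius_r0 "
                f"({self.wall_thickness_h} >= {self.radius_r0})"
            )

    @property
    def area(self) -> float:
        """Lumen cross-sectional area pi*r0^2 in m^2."""
        return math.pi * self.radius_r0**2


@dataclass(frozen=True)
class AnalogRLC:
    """Lumped electrical-analog values of a vessel segment (SI hydraulic units)."""

    resistance_R: float  # Pa s m^-3
    inertance_L: float  # kg m^-4
    compliance_C: float  # m^3 Pa^-1

    def __post_init__(self) -> None:
        if self.resistance_R <= 0 or self.inertance_L <= 0 or self.compliance_C <= 0:
            raise ValueError("all analog element values must be strictly positive")


def vessel_resistance(v: VesselSegment) -> float:
    """Poiseuille hydraulic resistance 8*mu*l/(pi*r^4) in Pa.s/m^3."""
    return 8.0 * v.viscosity_mu * v.length_l / (math.pi * v.radius_r0**4)


def vessel_inertance(v: VesselSegment) -> float:
    """Fluid inertance rho*l/(pi*r^2) in kg/m^4."""
    return v.density_rho * v.length_l / (math.pi * v.radius_r0**2)


def vessel_compliance(v: VesselSegment) -> float:
    """Thin-wall volume compliance 3*pi*r^3*l/(2*E*h) in m^3/Pa."""
    return 3.0 * math.pi * v.radius_r0**3 * v.length_l / (2.0 * v.youngs_E * v.wall_thickness_h)


def vessel_to_rlc(v: VesselSegment) -> AnalogRLC:
    """Map a vessel segment to its lumped R/L/C analog."""
    return AnalogRLC(
        resistance_R=vessel_resistance(v),
        inertance_L=vessel_inertance(v),
        compliance_C=vessel_compliance(v),
    )


# Accepted config-key unit suffixes and the factor converting them to SI.
_UNIT_SUFFIXES: dict[str, float] = {
    "_m": 1.0,
    "_mm": 1e-3,
    "_cm": 1e-2,
    "_pa": 1.0,
    "_kpa": 1e3,
    "_mpa": 1e6,
    "_pas": 1.0,
    "_mpas": 1e-3,
    "_kgm3": 1.0,
}

_FIELD_BASE = {
    "length": "length_l",
    "length_l": "length_l",
    "radius": "radius_r0",
    "radius_r0": "radius_r0",
    "wall_thickness": "wall_thickness_h",
    "wall_thickness_h": "wall_thickness_h",
    "youngs": "youngs_E",
    "youngs_e": "youngs_E",
    "density": "density_rho",
    "density_rho": "density_rho",
    "viscosity": "viscosity_mu",
    "viscosity_mu": "viscosity_mu",
}


def vessel_from_config(cfg: Mapping[str, Any]) -> VesselSegment:
    """Build a :class:`VesselSegment` from a JSON-style mapping.

    Keys mirror the field names and may carry an explicit unit suffix which is
    converted on entry, e.g. ``length_mm``, ``radius_mm``, ``viscosity_mPas``,
    ``youngs_MPa``.  Unsuffixed field names are taken as SI.
    """
    values: dict[str, float] = {}
    for key, raw in cfg.items():
        lk = key.lower()
        factor = 1.0
        base = lk
        for suffix, f in _UNIT_SUFFIXES.items():
            if lk.endswith(suffix) and lk[: -len(suffix)] in _FIELD_BASE:
                base, factor = lk[: -len(suffix)], f
                break
        if base not in _FIELD_BASE:
            raise KeyError(f"unrecognised vessel config key: {key!r}")
        field = _FIELD_BASE[base]
        if field in values:
            raise ValueError(f"duplicate vessel config entry for {field!r} (key {key!r})")
        values[field] = float(raw) * factor
    missing = {f for f in _FIELD_BASE.values()} - set(values)
    if missing:
        raise KeyError(f"vessel config missing fields: {sorted(missing)}")
    return VesselSegment(**values)
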
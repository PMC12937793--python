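"""0D surrogate model of a focal arterial stenosis.

A short cosine-profiled throat of length ``Ls`` inside a straight segment is
reduced to three additive pressure-loss contributions at flow ``Q``:

* baseline viscous loss over the full segment at the reference radius,
  ``8 mu l Q / (pi r0^4)``;
* throat viscous loss over ``Ls`` at the reduced radius ``rs = r0 (1 - sigma)``
  (present only for ``sigma > 0``);
* a minor (form) loss from flow separation, ``1/2 rho zeta (Q/As)^2`` with
  ``beta = As/A0 = (1 - sigma)^2`` and ``zeta = (1/beta - 1)^2``.

``sigma`` is the fractional *diameter* reduction.  Distal pressure follows as
``Pd = Pa - dP`` and fractional flow reserve as ``FFR = Pd/Pa`` (clamped to
[0, 1] for reporting; the raw value is kept).  Throat velocity ``V = Q/As``
and Poiseuille wall shear stress ``tau_w = 4 mu Q / (pi rs^3)`` complete the
output set.

The default composition mode ``"additive-throat"`` adds the throat loss on
top of the full-length baseline; ``"replace-throat"`` subtracts the throat
window's reference-radius contribution first, which is the physically
consistent serial decomposition but is not the default reporting convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import ML_PER_S, MMHG_PA, VesselSegment, pa_to_mmhg

__all__ = [
    "StenosisSpec",
    "FlowCondition",
    "HemoResult",
    "throat_radius",
    "loss_coefficient",
    "form_loss",
    "total_pressure_loss",
    "throat_velocity",
    "wall_shear",
    "severity_class",
    "stenosis_sweep",
    "surrogate_maps",
    "REFERENCE_VESSEL",
    "SIGMA_GRID",
]

#: The reference epicardial segment used for the stenosis sweep:
#: l = 30 mm, r0 = 1.5 mm, h = 0.2 r0, E = 0.4 MPa, rho = 1060, mu = 3.5e-3.
REFERENCE_VESSEL = VesselSegment(
    length_l=0.03,
    radius_r0=1.5e-3,
    wall_thickness_h=0.2 * 1.5e-3,
    youngs_E=0.4e6,
    density_rho=1060.0,
    viscosity_mu=3.5e-3,
)

#: Canonical severity grid (fractional diameter reduction).
SIGMA_GRID = (0.0, 0.25, 0.50, 0.75, 0.90)


def _check_sigma(sigma: float) -> None:
    if not (0.0 <= sigma < 1.0):
        raise ValueError(f"sigma must lie in [0, 1), got {sigma!r}")


@dataclass(frozen=True)
class StenosisSpec:
    """Focal stenosis description.

    ``sigma`` is the fractional diameter reduction in [0, 1);
    ``throat_length_Ls`` (m) must not exceed the host vessel length.
    """

    sigma: float
    throat_length_Ls: float
    vessel: VesselSegment

    def __post_init__(self) -> None:
        _check_sigma(self.sigma)
        if not (0.0 < self.throat_length_Ls <= self.vessel.length_l):
            raise ValueError(
                "throat_length_Ls must satisfy 0 < Ls <= vessel length "
                f"(Ls={self.throat_length_Ls}, l={self.vessel.length_l})"
            )

    @property
    def throat_radius_rs(self) -> float:
        return throat_radius(self.sigma, self.vessel.radius_r0)

    @property
    def throat_area_As(self) -> float:
        beta, _ = loss_coefficient(self.sigma)
        return beta * self.vessel.area


@dataclass(frozen=True)
class FlowCondition:
    """Steady flow state: volumetric flow (m^3/s) and proximal pressure (Pa)."""

    flow_Q: float
    proximal_pressure_Pa: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.flow_Q <= 0:
            raise ValueError(f"flow_Q must be > 0, got {self.flow_Q!r}")
        if self.proximal_pressure_Pa <= 0:
            raise ValueError(
                f"proximal_pressure_Pa must be > 0, got {self.proximal_pressure_Pa!r}"
            )


#: Resting and hyperemic conditions: Q = 1.0 / 3.0 mL/s at Pa = 100 mmHg.
REST = FlowCondition(flow_Q=1.0 * ML_PER_S, proximal_pressure_Pa=100 * MMHG_PA, label="rest")
HYPEREMIA = FlowCondition(flow_Q=3.0 * ML_PER_S, proximal_pressure_Pa=100 * MMHG_PA, label="hyperemia")


@dataclass(frozen=True)
class HemoResult:
    """Full 0D output set for one (stenosis, flow) pair.  Pressures in Pa."""

    dp_baseline: float
    dp_throat: float
    dp_form: float
    dp_total: float
    distal_pressure_Pd: float
    ffr_raw: float
    ffr: float
    throat_velocity: float
    wss_throat: float
    throat_radius_rs: float
    area_ratio_beta: float
    loss_coeff_zeta: float

    @property
    def dp_total_mmhg(self) -> float:
        return pa_to_mmhg(self.dp_total)

    @property
    def clamped(self) -> bool:
        """True when the raw FFR fell below zero and was clamped."""
        return self.ffr_raw < 0.0


def throat_radius(sigma: float, r0: float) -> float:
    """Reduced throat radius rs = r0*(1 - sigma)."""
    _check_sigma(sigma)
    if r0 <= 0:
        raise ValueError(f"r0 must be > 0, got {r0!r}")
    return r0 * (1.0 - sigma)


def loss_coefficient(sigma: float) -> tuple[float, float]:
    """Area ratio and separation-loss coefficient, (beta, zeta).

    beta = As/A0 = (1 - sigma)^2 and zeta = (1/beta - 1)^2; zeta vanishes for
    the healthy vessel and grows like (1 - sigma)^-4 toward occlusion.
    """
    _check_sigma(sigma)
    beta = (1.0 - sigma) ** 2
    zeta = (1.0 / beta - 1.0) ** 2
    return beta, zeta


def form_loss(sigma: float, vessel: VesselSegment, Q: float) -> float:
    """Minor (separation) pressure loss 1/2*rho*zeta*(Q/As)^2 in Pa."""
    _check_sigma(sigma)
    if Q <= 0:
        raise ValueError(f"Q must be > 0, got {Q!r}")
    beta, zeta = loss_coefficient(sigma)
    if zeta == 0.0:
        return 0.0
    a_s = beta * vessel.area
    return 0.5 * vessel.density_rho * zeta * (Q / a_s) ** 2


def throat_velocity(spec: StenosisSpec, Q: float) -> float:
    """Mean throat velocity V = Q/As (m/s); reduces to Q/A0 at sigma = 0."""
    if Q <= 0:
        raise ValueError(f"Q must be > 0, got {Q!r}")
    return Q / spec.throat_area_As


def wall_shear(spec: StenosisSpec, Q: float) -> float:
    """Poiseuille wall shear stress at the throat, 4*mu*Q/(pi*rs^3) in Pa."""
    if Q <= 0:
        raise ValueError(f"Q must be > 0, got {Q!r}")
    rs = spec.throat_radius_rs
    return 4.0 * spec.vessel.viscosity_mu * Q / (math.pi * rs**3)


def total_pressure_loss(
    spec: StenosisSpec,
    cond: FlowCondition,
    mode: str = "additive-throat",
) -> HemoResult:
    """Composite pressure loss, FFR, throat velocity and WSS for one state.

    ``mode="additive-throat"`` (default) adds the throat viscous loss on top
    of the full-length baseline; ``mode="replace-throat"`` removes the throat
    window's baseline share before adding the reduced-radius term.
    """
    if mode not in ("additive-throat", "replace-throat"):
        raise ValueError(f"unknown composition mode {mode!r}")
    v, Q = spec.vessel, cond.flow_Q
    dp_baseline = 8.0 * v.viscosity_mu * v.length_l * Q / (math.pi * v.radius_r0**4)
    if spec.sigma > 0.0:
        rs = spec.throat_radius_rs
        dp_throat = 8.0 * v.viscosity_mu * spec.throat_length_Ls * Q / (math.pi * rs**4)
        if mode == "replace-throat":
            dp_throat -= (
                8.0 * v.viscosity_mu * spec.throat_length_Ls * Q / (math.pi * v.radius_r0**4)
            )
    else:
        dp_throat = 0.0
    dp_form = form_loss(spec.sigma, v, Q)
    dp_total = dp_baseline + dp_throat + dp_form
    pa = cond.proximal_pressure_Pa
    if dp_total > pa:
        warnings.warn(
            f"pressure loss {pa_to_mmhg(dp_total):.4g} mmHg exceeds proximal pressure; "
            "FFR clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    ffr_raw = 1.0 - dp_total / pa
    beta, zeta = loss_coefficient(spec.sigma)
    return HemoResult(
        dp_baseline=dp_baseline,
        dp_throat=dp_throat,
        dp_form=dp_form,
        dp_total=dp_total,
        distal_pressure_Pd=pa - dp_total,
        ffr_raw=ffr_raw,
        ffr=max(0.0, ffr_raw),
        throat_velocity=throat_velocity(spec, Q),
        wss_throat=wall_shear(spec, Q),
        throat_radius_rs=spec.throat_radius_rs,
        area_ratio_beta=beta,
        loss_coeff_zeta=zeta,
    )


def severity_class(sigma: float) -> str:
    """Clinical severity bin for a fractional diameter reduction.

    Half-open bins covering [0, 1): mild < 0.30 <= moderate < 0.70 <=
    severe < 0.90 <= critical.
    """
    _check_sigma(sigma)
    if sigma < 0.30:
        return "mild"
    if sigma < 0.70:
        return "moderate"
    if sigma < 0.90:
        return "severe"
    return "critical"


def _format_ffr(res: HemoResult) -> str:
    return "~0.00" if res.clamped else f"{res.ffr:.3f}"


def stenosis_sweep(
    sigmas: Sequence[float] = SIGMA_GRID,
    conditions: Sequence[FlowCondition] = (REST, HYPEREMIA),
    vessel: VesselSegment = REFERENCE_VESSEL,
    throat_length_Ls: float = 5e-3,
    mode: str = "additive-throat",
) -> pd.DataFrame:
    """Evaluate the 0D model over a severity grid under one or more flows.

    Returns one row per (sigma, condition) with pressures in mmHg, the
    clamped FFR plus its raw value and an oscilloscope-style ``ffr_display``
    (clamped rows render as ``~0.00``).  Per-row failures are flagged in an
    ``error`` column instead of aborting the sweep.
    """
    rows = []
    for sigma in sigmas:
        for cond in conditions:
            row: dict = {
                "sigma": sigma,
                "condition": cond.label or f"Q={cond.flow_Q / ML_PER_S:g} mL/s",
                "Q_mLs": cond.flow_Q / ML_PER_S,
                "error": "",
            }
            try:
                spec = StenosisSpec(sigma=sigma, throat_length_Ls=throat_length_Ls, vessel=vessel)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = total_pressure_loss(spec, cond, mode=mode)
            except ValueError as exc:
                row["error"] = str(exc)
                rows.append(row)
                continue
            row.update(
                dP_mmHg=res.dp_total_mmhg,
                FFR=res.ffr,
                FFR_raw=res.ffr_raw,
                ffr_display=_format_ffr(res),
                clamped=res.clamped,
                V_mps=res.throat_velocity,
                WSS_Pa=res.wss_throat,
                severity=severity_class(sigma),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def surrogate_maps(
    sigma_grid: Iterable[float],
    q_grid_mLs: Iterable[float],
    vessel: VesselSegment = REFERENCE_VESSEL,
    throat_length_Ls: float = 5e-3,
    proximal_pressure_mmhg: float = 100.0,
    log10_wss: bool = False,
) -> pd.DataFrame:
    """Dense (sigma x Q) maps of pressure loss, WSS and throat velocity.

    Long-format frame with columns sigma, Q_mLs, dP_mmHg, WSS_Pa (optionally
    log10), V_mps — the plotting-ready surrogate fields.
    """
    sigmas = np.asarray(list(sigma_grid), dtype=float)
    qs = np.asarray(list(q_grid_mLs), dtype=float)
    if sigmas.size == 0 or qs.size == 0:
        raise ValueError("sigma and Q grids must be non-empty")
    records = []
    for sigma in sigmas:
        spec = StenosisSpec(sigma=float(sigma), throat_length_Ls=throat_length_Ls, vessel=vessel)
        for q in qs:
            cond = FlowCondition(
                flow_Q=float(q) * ML_PER_S,
                proximal_pressure_Pa=proximal_pressure_mmhg * MMHG_PA,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = total_pressure_loss(spec, cond)
            wss = math.log10(res.wss_throat) if log10_wss else res.wss_throat
            records.append(
                {
                    "sigma": float(sigma),
                    "Q_mLs": float(q),
                    "dP_mmHg": res.dp_total_mmhg,
                    "WSS_Pa": wss,
                    "V_mps": res.throat_velocity,
                }
            )
    return pd.DataFrame(records)
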
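"""Pulsatile driving of the 0D stenosis model and a three-element Windkessel.

The physical board is excited with a fixed 50 Hz sinusoid, not a cardiac
waveform, so pulsatile physiology is explored on the simulation side: a
sinusoidal flow waveform Q(t) = Q_mean + Q_amp sin(2 pi f t) at a heart-rate
frequency (1.2-1.5 Hz) drives the steady 0D model sample by sample
(quasi-steady assumption — the lesion's pressure loss responds
instantaneously to flow, valid when the throat transit time is short against
the pulse period).  Because dP(Q) is convex for sigma > 0, the cycle-mean
loss exceeds the loss at the mean flow.

The three-element Windkessel terminal load (characteristic impedance Z,
peripheral resistance R, compliance C, venous pressure taken as zero)
is integrated in the standard split form p = Z q + p_c with
C dp_c/dt = q - p_c/R, equivalent to p + RC dp/dt = (Z+R) q + ZRC dq/dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stenosis import FlowCondition, StenosisSpec, total_pressure_loss
from .units import MMHG_PA

__all__ = [
    "FlowWaveform",
    "WindkesselSpec",
    "sample_waveform",
    "quasi_steady_dp",
    "wk3_pressure",
]


@dataclass(frozen=True)
class FlowWaveform:
    """Sinusoidal volumetric flow waveform (SI units).

    ``mean_Q`` must exceed ``amplitude_Q`` so the flow never reverses.
    """

    mean_Q: float
    amplitude_Q: float
    frequency: float = 1.2
    n_cycles: int = 5
    samples_per_cycle: int = 200

    def __post_init__(self) -> None:
        if not (self.mean_Q > self.amplitude_Q >= 0.0):
            raise ValueError("require mean_Q > amplitude_Q >= 0 (flow stays positive)")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency!r}")
        if self.n_cycles < 1 or self.samples_per_cycle < 2:
            raise ValueError("need >= 1 cycle and >= 2 samples per cycle")


@dataclass(frozen=True)
class WindkesselSpec:
    """Three-element Windkessel terminal load (SI hydraulic units)."""

    char_impedance_Z: float  # Pa s m^-3
    peripheral_R: float  # Pa s m^-3
    compliance_C: float  # m^3 Pa^-1

    def __post_init__(self) -> None:
        if min(self.char_impedance_Z, self.peripheral_R, self.compliance_C) <= 0:
            raise ValueError("all Windkessel elements must be strictly positive")


def sample_waveform(w: FlowWaveform) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sampled (t, Q) series over ``n_cycles`` whole cycles."""
    n = w.n_cycles * w.samples_per_cycle
    dt = 1.0 / (w.frequency * w.samples_per_cycle)
    t = np.arange(n) * dt
    q = w.mean_Q + w.amplitude_Q * np.sin(2.0 * np.pi * w.frequency * t)
    return t, q


def quasi_steady_dp(
    spec: StenosisSpec,
    w: FlowWaveform,
    proximal_pressure_Pa: float = 100 * MMHG_PA,
) -> dict:
    """Quasi-steady pressure-loss time series dP(t) for a pulsatile flow.

    Applies the steady 0D model sample by sample.  Returns the series plus
    final-cycle summary statistics (mean/max/min, mmHg).
    """
    t, q = sample_waveform(w)
    dp = np.empty_like(q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, qi in enumerate(q):
            cond = FlowCondition(flow_Q=float(qi), proximal_pressure_Pa=proximal_pressure_Pa)
            dp[i] = total_pressure_loss(spec, cond).dp_total
    last = dp[-w.samples_per_cycle :]
    return {
        "t_s": t,
        "Q_m3s": q,
        "dP_Pa": dp,
        "dP_mmHg": dp / MMHG_PA,
        "cycle_mean_mmHg": float(last.mean() / MMHG_PA),
        "cycle_max_mmHg": float(last.max() / MMHG_PA),
        "cycle_min_mmHg": float(last.min() / MMHG_PA),
    }


def wk3_pressure(q: np.ndarray, wk: WindkesselSpec, dt: float) -> np.ndarray:
    """Integrate the three-element Windkessel: pressure series for flow ``q``.

    Trapezoidal (Crank-Nicolson) update of the compliance-chamber pressure
    p_c from p_c(0) = 0, then p = Z q + p_c.  Steady flow converges to
    p = (Z + R) q; a very large C pins p near Z q.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size < 2:
        raise ValueError("need a 1-D flow series with >= 2 samples")
    Z, R, C = wk.char_impedance_Z, wk.peripheral_R, wk.compliance_C
    tau = R * C
    pc = np.zeros_like(q)
    # trapezoidal rule on C dpc/dt = q - pc/R
    a = 1.0 + dt / (2.0 * tau)
    b = 1.0 - dt / (2.0 * tau)
    for i in range(1, q.size):
        pc[i] = (b * pc[i - 1] + (dt / (2.0 * C)) * (q[i] + q[i - 1])) / a
    return Z * q + pc
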
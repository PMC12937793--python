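"""Pressure-voltage calibration of the analog board.

A single constant k_P (V per mmHg) links measured voltage differences to
pressure differences.  The board's voltage outputs scale as dU = k_P * dP,
so a measured voltage difference converts to pressure by division:
dP = dU / k_P.  (The two directions are easy to confuse because k_P carries
V/mmHg; the division form is the one consistent with those units and with
the shipped reference tables.)  The default constant is the experimentally
calibrated k_P = 0.125 V/mmHg.

k_P is fitted from paired (dU, dP_ref) data by least squares through the
origin — a zero voltage difference must map to zero pressure difference —
with a case-resampling percentile bootstrap for the 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["K_P_DEFAULT", "CalibrationFit", "voltage_to_pressure", "fit_kp"]

#: Experimentally calibrated conversion constant, V per mmHg.
K_P_DEFAULT = 0.125


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted conversion constant with 95% CI and goodness of fit."""

    k_P: float
    ci95: tuple[float, float]
    r_squared: float
    n_pairs: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.k_P <= hi):
            raise ValueError("ci95 must bracket the point estimate")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")


def voltage_to_pressure(dU: float, k_P: float = K_P_DEFAULT) -> float:
    """Convert a voltage difference (V) to a pressure difference (mmHg)."""
    if k_P <= 0:
        raise ValueError(f"k_P must be > 0, got {k_P!r}")
    return dU / k_P


def _kp_point(dU: np.ndarray, dP: np.ndarray) -> float:
    # least squares through the origin of dU on dP
    return float(np.dot(dP, dU) / np.dot(dP, dP))


def fit_kp(
    pairs: Sequence[tuple[float, float]],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CalibrationFit:
    """Fit k_P from (dU volts, dP_ref mmHg) pairs.

    Origin-constrained least squares gives the point estimate; a seeded
    case-resampling percentile bootstrap (default 1000 draws) gives the 95%
    CI.  R^2 is computed from the origin-constrained fit against the
    centered total sum of squares and clipped to [0, 1].
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (dU, dP_ref) pairs")
    dU, dP = arr[:, 0], arr[:, 1]
    if np.ptp(dP) == 0.0:
        raise ValueError("dP_ref values must not all be identical")
    k = _kp_point(dU, dP)
    resid = dU - k * dP
    ss_tot = float(np.sum((dU - dU.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else float(np.clip(1.0 - np.sum(resid**2) / ss_tot, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    draws = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        dPs = dP[idx]
        if np.dot(dPs, dPs) == 0.0:  # degenerate resample; redraw deterministic fallback
            draws[i] = k
        else:
            draws[i] = _kp_point(dU[idx], dPs)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo, hi = min(lo, k), max(hi, k)
    return CalibrationFit(k_P=k, ci95=(float(lo), float(hi)), r_squared=r2, n_pairs=n)
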
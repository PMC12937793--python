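"""Clinical PAD quantities and concordance with the analog board's outputs.

Ankle-brachial index (ABI), Doppler peak-systolic-velocity ratio (PSVR)
grading, the simplified-Bernoulli translesional gradient
dP_clin = 4 (V_sten^2 - V_prox^2) (velocities in m/s, gradient in mmHg; the
factor 4 folds the kinetic-energy term 1/2 rho v^2 and the Pa->mmHg
conversion for blood density ~1060 kg/m^3), and severity-group concordance
between Doppler-derived gradients and board-equivalent pressures
dP_eq = dU / k_P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import K_P_DEFAULT, voltage_to_pressure
from .stats import pearson_r

__all__ = [
    "PatientRecord",
    "CohortGroup",
    "abi",
    "psvr",
    "psvr_grade",
    "bernoulli_dp",
    "patient_summary",
    "cohort_concordance",
]


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient vascular measurements (pressures mmHg, velocities m/s)."""

    brachial_systolic: float
    ankle_systolic_left: float
    ankle_systolic_right: float
    psv_stenosis: float
    psv_proximal: float

    def __post_init__(self) -> None:
        if min(self.brachial_systolic, self.ankle_systolic_left, self.ankle_systolic_right) <= 0:
            raise ValueError("systolic pressures must be strictly positive")
        if self.psv_stenosis < 0 or self.psv_proximal <= 0:
            raise ValueError("require psv_stenosis >= 0 and psv_proximal > 0")


@dataclass(frozen=True)
class CohortGroup:
    """Severity-group summary (mean +/- sd per quantity)."""

    label: str
    n: int
    psv_mean: float
    psv_sd: float
    dp_clin_mean: float
    dp_clin_sd: float
    abi_mean: float
    abi_sd: float
    du_mean: float
    du_sd: float
    dp_eq_mean: float
    dp_eq_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("psv_sd", "dp_clin_sd", "abi_sd", "du_sd", "dp_eq_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def abi(brachial: float, ankle_left: float, ankle_right: float) -> float:
    """Ankle-brachial index: the lower ankle pressure over the brachial one."""
    if brachial <= 0:
        raise ValueError(f"brachial pressure must be > 0, got {brachial!r}")
    if min(ankle_left, ankle_right) <= 0:
        raise ValueError("ankle pressures must be > 0")
    return min(ankle_left, ankle_right) / brachial


def psvr(psv_sten: float, psv_prox: float) -> float:
    """Peak systolic velocity ratio PSV_stenosis / PSV_proximal."""
    if psv_prox <= 0:
        raise ValueError(f"proximal velocity must be > 0, got {psv_prox!r}")
    if psv_sten < 0:
        raise ValueError(f"stenotic velocity must be >= 0, got {psv_sten!r}")
    return psv_sten / psv_prox


def psvr_grade(ratio: float) -> str:
    """Duplex severity grade from PSVR.

    < 2.0 -> ``normal/mild`` (< 30% stenosis); 2.0-4.0 inclusive ->
    ``moderate`` (30-69%); > 4.0 -> ``severe/critical`` (>= 70%).
    """
    if ratio <= 0:
        raise ValueError(f"PSVR must be > 0, got {ratio!r}")
    if ratio < 2.0:
        return "normal/mild"
    if ratio <= 4.0:
        return "moderate"
    return "severe/critical"


def bernoulli_dp(v_sten: float, v_prox: float) -> float:
    """Simplified-Bernoulli gradient 4 (v_sten^2 - v_prox^2) in mmHg.

    Antisymmetric in its arguments; a negative result (retrograde gradient)
    is returned with a warning rather than rejected.
    """
    dp = 4.0 * (v_sten**2 - v_prox**2)
    if dp < 0:
        warnings.warn(
            "stenotic velocity below proximal velocity: negative gradient",
            RuntimeWarning,
            stacklevel=2,
        )
    return dp


def patient_summary(rec: PatientRecord) -> dict:
    """Derived indices for one patient: ABI, PSVR + grade, Bernoulli gradient."""
    ratio = psvr(rec.psv_stenosis, rec.psv_proximal)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dp = bernoulli_dp(rec.psv_stenosis, rec.psv_proximal)
    return {
        "abi": abi(rec.brachial_systolic, rec.ankle_systolic_left, rec.ankle_systolic_right),
        "abi_flag_above_1": abi(
            rec.brachial_systolic, rec.ankle_systolic_left, rec.ankle_systolic_right
        )
        > 1.0,
        "psvr": ratio,
        "grade": psvr_grade(ratio),
        "dp_clin_mmHg": dp,
    }


_REQUIRED_COLS = ("label", "dP_clin_mmHg", "ABI", "dU_V")


def cohort_concordance(groups: pd.DataFrame, k_P: float = K_P_DEFAULT) -> dict:
    """Group-level concordance of Doppler gradients with board equivalents.

    ``groups`` needs columns ``label``, ``dP_clin_mmHg``, ``ABI``, ``dU_V``
    (group means).  Returns the per-group dP_eq = dU/k_P and Pearson
    correlations of dP_eq with dP_clin and with ABI.
    """
    missing = [c for c in _REQUIRED_COLS if c not in groups.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(groups) < 3:
        raise ValueError("need >= 3 severity groups")
    dp_eq = np.array([voltage_to_pressure(du, k_P) for du in groups["dU_V"]])
    out = groups.copy()
    out["dP_eq_mmHg"] = dp_eq
    return {
        "table": out,
        "r_dp_clin_vs_dp_eq": pearson_r(groups["dP_clin_mmHg"], dp_eq),
        "r_abi_vs_dp_eq": pearson_r(groups["ABI"], dp_eq),
        "k_P": k_P,
    }
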
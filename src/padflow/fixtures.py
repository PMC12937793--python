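"""Packaged reference tables and seeded synthetic generators.

Three measured/derived reference tables ship as CSV resources so every
module is testable offline:

* ``pcb_sweep_reference`` — the 40-level oscilloscope sweep of the physical
  board (input voltage, mean output voltage, peak-to-peak and rectified-mean
  amplitudes).  Rows are stored sorted by test index; two rows were recorded
  out of order in the original log (34 before 33) and one rectified-mean
  entry carried a trailing stray character — values are preserved, order and
  typo normalised.  This is a hardware measurement artefact: the circuit
  solver is not expected to regenerate it numerically.
* ``stenosis_reference`` — the 0D model's pressure-loss/FFR table over the
  canonical severity grid.  FFR cells printed as "~0.00" are stored as 0.0
  with a ``clamped`` flag; the two hyperemic cells at 75%/90% carry a
  ``hyper_unit_suspect`` flag (the printed numbers equal the model's value
  in pascals, not mmHg).
* ``pad_cohort_reference`` — severity-group summaries of the 20-patient PAD
  cohort (PSV, Bernoulli gradient, ABI, board voltage difference and its
  pressure equivalent).  The censored "<2 mmHg" gradient of the normal group
  is stored as 1.0 +/- 0.5 with the censoring note kept alongside.

The synthetic generators emulate the sweep's flat-then-steep signature and
noiseless/noisy calibration pairs; all take explicit seeds.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_pcb_sweep",
    "load_stenosis_reference",
    "load_pad_cohort",
    "synth_sweep",
    "synth_calibration_pairs",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("padflow.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_pcb_sweep() -> pd.DataFrame:
    """40-row board sweep recording (test, Uin_V, Uoff_V, Vpp_mV, Vavg_mV)."""
    df = _load("pcb_sweep_reference.csv")
    sentinel = (
        len(df) == 40
        and df["Uoff_V"].iloc[0] == 3.520
        and df["Uoff_V"].iloc[-1] == 5.421
        and df["Vpp_mV"].iloc[-1] == 32190.56
    )
    if not sentinel:
        raise ValueError("pcb_sweep_reference.csv failed its integrity check")
    df["resistance_fraction"] = 0.025 * df["test"]
    return df


def load_stenosis_reference() -> pd.DataFrame:
    """0D pressure-loss/FFR reference over sigma = 0, 0.25, 0.5, 0.75, 0.9."""
    df = _load("stenosis_reference.csv")
    if len(df) != 5 or df["dP_rest_mmHg"].iloc[2] != 12.91:
        raise ValueError("stenosis_reference.csv failed its integrity check")
    for col in ("FFR_rest_clamped", "FFR_hyper_clamped", "hyper_unit_suspect"):
        df[col] = df[col].astype(bool)
    return df


def load_pad_cohort() -> pd.DataFrame:
    """Severity-group summaries of the PAD cohort (n sums to 20)."""
    df = _load("pad_cohort_reference.csv")
    if len(df) != 5 or int(df["n"].sum()) != 20:
        raise ValueError("pad_cohort_reference.csv failed its integrity check")
    return df


def synth_sweep(
    n_levels: int = 40,
    baseline_u: float = 3.52,
    inflection_level: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic sweep recording with the flat-then-steep signature.

    The mean output curve is a continuous hinge in the resistance fraction
    (gentle pre-inflection slope, steep post-inflection slope) plus seeded
    Gaussian noise; companion Uin/Vpp/Vavg columns follow the same shape.
    Deterministic for a fixed seed; ``noise_sd=0`` gives an exactly monotone
    non-decreasing output column.
    """
    if n_levels < 4:
        raise ValueError("need n_levels >= 4")
    if not (0.0 < inflection_level < 1.0):
        raise ValueError("inflection_level must lie in (0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    level = np.arange(1, n_levels + 1) / n_levels
    hinge = np.maximum(0.0, level - inflection_level)
    u_off = baseline_u + 0.2 * level + 3.6 * hinge
    u_in = 4.9 + 0.4 * level + 2.2 * hinge
    v_pp = 383.0 + 400.0 * level + 30000.0 * hinge**2
    v_avg = 41.0 + 300.0 * level + 2200.0 * hinge**2
    if noise_sd > 0:
        u_off = u_off + rng.normal(0.0, noise_sd, n_levels)
        u_in = u_in + rng.normal(0.0, noise_sd, n_levels)
        v_pp = v_pp + rng.normal(0.0, 1e3 * noise_sd, n_levels)
        v_avg = v_avg + rng.normal(0.0, 1e3 * noise_sd, n_levels)
    return pd.DataFrame(
        {
            "test": np.arange(1, n_levels + 1),
            "resistance_fraction": level,
            "Uin_V": u_in,
            "Uoff_V": u_off,
            "Vpp_mV": v_pp,
            "Vavg_mV": v_avg,
        }
    )


def synth_calibration_pairs(
    n: int = 20,
    k_P_true: float = 0.125,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (dU_V, dP_mmHg) calibration data on a fixed pressure grid.

    ``dP_mmHg`` spans 2-45 mmHg; ``dU_V = k_P_true * dP`` with optional
    multiplicative Gaussian noise of relative standard deviation
    ``noise_sd`` (e.g. 0.02 for 2% of each voltage).
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    rng = np.random.default_rng(seed)
    dp = np.linspace(2.0, 45.0, n)
    du = k_P_true * dp
    if noise_sd > 0:
        du = du * (1.0 + rng.normal(0.0, noise_sd, n))
    return pd.DataFrame({"dU_V": du, "dP_mmHg": dp})
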
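"""Quantitative-analysis toolkit for model-experiment comparison.

Normalisation of sweep curves, quadratic and hinge (breakpoint) fits with
seeded bootstrap confidence intervals, Pearson r / RMSE agreement metrics,
discrete Fréchet curve similarity, the slope-doubling severity estimate,
one-at-a-time (OAT) parameter sensitivity and replicate repeatability
statistics.  All randomness is explicit: every bootstrap takes a seed
(default 0) and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CurveFit",
    "BreakpointFit",
    "RepeatabilityReport",
    "normalize_curve",
    "quadratic_fit",
    "breakpoint_fit",
    "slope_doubling_sigma",
    "pearson_r",
    "rmse",
    "frechet_distance",
    "oat_sensitivity",
    "repeatability_stats",
]


@dataclass(frozen=True)
class CurveFit:
    """Quadratic fit record: y = a0 + a1*x + a2*x^2."""

    a0: float
    a1: float
    a2: float
    r_squared: float
    rmse: float
    ci95: dict[str, tuple[float, float]]
    n: int
    seed: int

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)


@dataclass(frozen=True)
class BreakpointFit:
    """Continuous two-segment linear fit with a data-driven breakpoint."""

    breakpoint_sigma: float
    slope_left: float
    slope_right: float
    intercept: float
    sse: float
    ci95: tuple[float, float] | None


@dataclass(frozen=True)
class RepeatabilityReport:
    """Per-level replicate statistics and a first-vs-last drift t-test."""

    table: pd.DataFrame  # columns: level, mean, sd, cv
    drift_p_value: float


def normalize_curve(values: Sequence[float], baseline_index: int = 0) -> np.ndarray:
    """Divide a curve elementwise by its baseline value."""
    arr = np.asarray(values, dtype=float)
    base = arr[baseline_index]
    if base == 0.0:
        raise ValueError("baseline value is zero; cannot normalize")
    return arr / base


def _quad_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, x**2])


def quadratic_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CurveFit:
    """OLS fit of y = a0 + a1*x + a2*x^2 with percentile-bootstrap 95% CIs.

    Requires >= 3 distinct x values (otherwise the design is rank-deficient).
    For constant y the fit degenerates to the mean and R^2 is reported as 0
    by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values for a quadratic fit")
    X = _quad_design(x)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    fit_rmse = float(np.sqrt(ss_res / y.size))
    rng = np.random.default_rng(seed)
    n = x.size
    draws = np.empty((n_bootstrap, 3))
    for i in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        if np.unique(xb).size < 3:
            draws[i] = coef
            continue
        cb, *_ = np.linalg.lstsq(_quad_design(xb), y[idx], rcond=None)
        draws[i] = cb
    ci = {}
    for j, name in enumerate(("a0", "a1", "a2")):
        lo, hi = np.percentile(draws[:, j], [2.5, 97.5])
        ci[name] = (float(min(lo, coef[j])), float(max(hi, coef[j])))
    return CurveFit(
        a0=float(coef[0]),
        a1=float(coef[1]),
        a2=float(coef[2]),
        r_squared=r2,
        rmse=fit_rmse,
        ci95=ci,
        n=n,
        seed=seed,
    )


def _hinge_sse(x: np.ndarray, y: np.ndarray, c: float) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(np.sum(resid**2)), coef


def breakpoint_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_bootstrap: int = 0,
    seed: int = 0,
) -> BreakpointFit:
    """Continuous two-segment linear fit, breakpoint by grid search.

    Candidate breakpoints are the observed interior x values; the candidate
    minimising the SSE wins, ties broken toward the smallest x.  An optional
    seeded bootstrap over cases gives a percentile CI for the breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise ValueError("need >= 5 (x, y) points for a breakpoint fit")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    candidates = np.unique(x)[1:-1]
    if candidates.size == 0:
        raise ValueError("no interior candidate breakpoints")
    best_c, best_sse, best_coef = None, np.inf, None
    for c in candidates:
        sse, coef = _hinge_sse(x, y, float(c))
        # strict improvement only: ties keep the earliest (smallest) candidate
        if best_c is None or sse < best_sse - 1e-12 * max(1.0, sse):
            best_c, best_sse, best_coef = float(c), sse, coef
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = x.size
        bps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            cands = np.unique(xb)[1:-1]
            if cands.size == 0:
                continue
            cb, sb = None, np.inf
            for c in cands:
                sse, _ = _hinge_sse(xb, yb, float(c))
                if cb is None or sse < sb - 1e-12 * max(1.0, sse):
                    cb, sb = float(c), sse
            if cb is not None:
                bps.append(cb)
        if bps:
            lo, hi = np.percentile(bps, [2.5, 97.5])
            ci = (float(lo), float(hi))
    assert best_coef is not None
    return BreakpointFit(
        breakpoint_sigma=best_c,
        slope_left=float(best_coef[1]),
        slope_right=float(best_coef[1] + best_coef[2]),
        intercept=float(best_coef[0]),
        sse=best_sse,
        ci95=ci,
    )


def slope_doubling_sigma(fit: CurveFit) -> float:
    """Severity at which the quadratic's local slope doubles its initial value.

    Solves a1 + 2 a2 sigma = 2 a1, i.e. sigma* = a1 / (2 a2); defined only
    for positive a1 and a2 and only when the solution lies in [0, 1].
    """
    if fit.a1 <= 0 or fit.a2 <= 0:
        raise ValueError("slope-doubling severity requires a1 > 0 and a2 > 0")
    sigma = fit.a1 / (2.0 * fit.a2)
    if not (0.0 <= sigma <= 1.0):
        raise ValueError(f"slope-doubling severity {sigma:.4g} falls outside [0, 1]")
    return sigma


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with >= 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-square difference between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def frechet_distance(curve_a: Sequence[Sequence[float]], curve_b: Sequence[Sequence[float]]) -> float:
    """Discrete Fréchet distance between two polygonal curves of 2-D points.

    Standard dynamic-programming recurrence over the coupling lattice:
    d[i, j] = max(|a_i - b_j|, min(d[i-1, j], d[i-1, j-1], d[i, j-1])).
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("curves must be non-empty")
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("curves must be sequences of points")
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = dist.shape
    d = np.empty((n, m))
    d[0, 0] = dist[0, 0]
    for i in range(1, n):
        d[i, 0] = max(d[i - 1, 0], dist[i, 0])
    for j in range(1, m):
        d[0, j] = max(d[0, j - 1], dist[0, j])
    for i in range(1, n):
        for j in range(1, m):
            d[i, j] = max(dist[i, j], min(d[i - 1, j], d[i - 1, j - 1], d[i, j - 1]))
    return float(d[n - 1, m - 1])


def oat_sensitivity(
    model: Callable[..., np.ndarray],
    parameters: Mapping[str, float],
    perturbation: float = 0.20,
) -> pd.DataFrame:
    """One-at-a-time parameter sensitivity of a curve-valued model.

    ``model(**parameters)`` must return an output curve (1-D array).  Each
    parameter is perturbed by +/- ``perturbation`` (relative); the relative
    change of the curve at each grid point is tabulated.  Model failures are
    flagged per cell rather than raised.
    """
    base = np.asarray(model(**dict(parameters)), dtype=float)
    rows = []
    for name in parameters:
        for sign in (+1.0, -1.0):
            pert = dict(parameters)
            pert[name] = parameters[name] * (1.0 + sign * perturbation)
            row: dict = {"parameter": name, "direction": "+" if sign > 0 else "-", "error": ""}
            try:
                out = np.asarray(model(**pert), dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    rel = np.where(base != 0.0, (out - base) / base, out - base)
                row["relative_change"] = rel
                row["max_abs_change"] = float(np.max(np.abs(rel)))
            except Exception as exc:  # per-cell flagging, not aborting
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def repeatability_stats(runs: pd.DataFrame) -> RepeatabilityReport:
    """Replicate repeatability: per-level mean/SD/CV and a drift t-test.

    ``runs`` is indexed by measurement level with one column per independent
    series (all series on the identical level grid).  CV = SD/|mean|.  Drift
    is the two-sided paired t-test between the first and last series; for
    identical series the test is degenerate and p is reported as 1.
    """
    if runs.shape[1] < 2:
        raise ValueError("need >= 2 measurement series")
    if runs.isna().any().any():
        raise ValueError("mismatched level grids (missing values)")
    values = runs.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / np.abs(mean), np.inf)
        cv = np.where(sd == 0.0, 0.0, cv)
    table = pd.DataFrame({"level": runs.index, "mean": mean, "sd": sd, "cv": cv})
    first, last = values[:, 0], values[:, -1]
    if np.allclose(first, last):
        p = 1.0
    else:
        p = float(sps.ttest_rel(first, last).pvalue)
    return RepeatabilityReport(table=table, drift_p_value=p)
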
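"""Rescaled-range (R/S) Hurst exponent and the trend-persistence forecast.

For each window length m the series is cut into ⌊n/m⌋ blocks; each block
contributes its range of cumulative deviations from the block mean divided
by its (population) standard deviation, and block values are averaged.  H is
the slope of the least-squares fit of log(R/S) on log(m).  H > 0.5 means the
observed trend tends to persist, H < 0.5 that it tends to reverse, H = 0.5
that the future is unforecastable.  Superimposing H on the current trend
signs and re-classifying degradation yields the four-class transition map
(continuous improvement / degradation-to-improvement / improvement-to-
degradation / continuous degradation, plus indeterminate).

Plain (uncorrected) R/S is the default; the Anis-Lloyd small-sample expected
value correction is available behind a flag.  With only ~20 annual points H
is noisy, so the log-log fit R² is carried as a quality flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degradation import DEGRADED_LEVELS, DegradationMap, classify_degradation
from .grid import GridStack

__all__ = [
    "rs_hurst",
    "hurst_map",
    "HurstMap",
    "persistence_class",
    "forecast_dynamics",
    "ForecastMap",
    "TRANSITIONS",
]


def default_window_set(n: int, min_window: int = 8) -> np.ndarray:
    """Window lengths m: all integers min_window..n/2 for short series,
    ~12 log-spaced values for long ones."""
    if n < 2 * min_window:
        raise ValueError("series too short for R/S analysis")
    hi = n // 2
    if hi <= 3 * min_window:
        return np.arange(min_window, hi + 1)
    return np.unique(np.round(np.geomspace(min_window, hi, 12)).astype(int))


def _anis_lloyd(m: np.ndarray) -> np.ndarray:
    """Expected R/S of iid Gaussian noise at block length m (Anis-Lloyd,
    exact gamma form for small m, asymptotic form above 340)."""
    from scipy.special import gammaln

    out = np.empty(len(m), dtype=float)
    for k, n in enumerate(m):
        i = np.arange(1, n)
        s = np.sum(np.sqrt((n - i) / i))
        if n <= 340:
            front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
        else:
            front = ((n - 0.5) / n) / np.sqrt(n * np.pi / 2.0)
        out[k] = front * s
    return out


def rs_hurst(
    series: np.ndarray,
    min_window: int = 8,
    window_set: np.ndarray | None = None,
    correction: bool = False,
) -> tuple[float, float]:
    """Estimate the Hurst exponent of one series by R/S analysis.

    Returns ``(H, r_squared)`` with H clipped to (0, 1); ``(nan, nan)`` for
    series shorter than 16 points or blocks with zero variance (constant
    segments).  ``correction=True`` divides each R/S by the Anis-Lloyd
    iid expectation ratio before fitting (small-sample bias reduction).
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 16 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    ms = (default_window_set(n, min_window) if window_set is None
          else np.asarray(window_set, dtype=int))
    ms = ms[(ms >= 2) & (ms <= n)]
    rs = np.full(len(ms), np.nan)
    for k, m in enumerate(ms):
        nblocks = n // m
        blocks = x[: nblocks * m].reshape(nblocks, m)
        mean = blocks.mean(axis=1, keepdims=True)
        dev = np.cumsum(blocks - mean, axis=1)
        rng = dev.max(axis=1) - dev.min(axis=1)
        sd = blocks.std(axis=1)                      # population (1/m)
        ok = sd > 0
        if not ok.any():
            return float("nan"), float("nan")
        rs[k] = np.mean(rng[ok] / sd[ok])
    logs = np.log(ms)
    offset = 0.0
    logr = np.log(rs)
    if correction:
        # regress the deviation from the iid expectation; H = 0.5 + slope
        logr = logr - np.log(_anis_lloyd(ms))
        offset = 0.5
    A = np.column_stack([logs, np.ones(len(ms))])
    coef, *_ = np.linalg.lstsq(A, logr, rcond=None)
    fitted = A @ coef
    ss_res = ((logr - fitted) ** 2).sum()
    ss_tot = ((logr - logr.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    h = float(np.clip(coef[0] + offset, 1e-6, 1 - 1e-6))
    return h, float(r2)


@dataclass
class HurstMap:
    """Per-pixel Hurst exponent with log-log fit quality."""

    h: np.ndarray
    r_squared: np.ndarray

    @property
    def persistence(self) -> np.ndarray:
        """Object array: persistent | anti-persistent | unpredictable | ''."""
        out = np.full(self.h.shape, "", dtype=object)
        with np.errstate(invalid="ignore"):
            out[self.h > 0.5] = "persistent"
            out[self.h < 0.5] = "anti-persistent"
            out[self.h == 0.5] = "unpredictable"
        return out


def hurst_map(stack: GridStack, window_set: np.ndarray | None = None,
              correction: bool = False) -> HurstMap:
    """R/S Hurst exponent at every pixel of an annual stack.

    Pixels with nodata years, constant series, or length < 16 are nodata.
    """
    ny = stack.n_years
    flat = stack.values.reshape(ny, -1)
    h = np.full(flat.shape[1], np.nan)
    r2 = np.full(flat.shape[1], np.nan)
    ws = default_window_set(ny) if window_set is None else window_set
    ok = ~np.isnan(flat).any(axis=0)
    for k in np.flatnonzero(ok):
        h[k], r2[k] = rs_hurst(flat[:, k], window_set=ws, correction=correction)
    return HurstMap(h=h.reshape(stack.shape), r_squared=r2.reshape(stack.shape))


def persistence_class(h: float) -> str:
    """Threshold rule at H = 0.5: persistent / anti-persistent / unpredictable."""
    if h is None or (isinstance(h, float) and np.isnan(h)):
        return ""
    if not (0.0 < h < 1.0):
        raise ValueError(f"H must be in (0, 1), got {h}")
    if h > 0.5:
        return "persistent"
    if h < 0.5:
        return "anti-persistent"
    return "unpredictable"


TRANSITIONS = (
    "continuous improvement",
    "degradation to improvement",
    "improvement to degradation",
    "continuous degradation",
    "indeterminate",
)


@dataclass
class ForecastMap:
    """Forecast degradation level and four-class transition per pixel."""

    forecast_level: np.ndarray
    transition: np.ndarray

    def area_summary(self, cell_area: float = 1.0):
        import pandas as pd
        analyzed = self.transition != ""
        total = int(analyzed.sum())
        rows = []
        for t in TRANSITIONS:
            n = int((self.transition == t).sum())
            rows.append({"transition": t, "pixels": n, "area": n * cell_area,
                         "percent": 100.0 * n / total if total else np.nan})
        return pd.DataFrame(rows)


def _future_slope(slope: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Forecast slope sign: kept where H > 0.5, flipped where H < 0.5,
    NaN (indeterminate) at H = 0.5 or missing H."""
    out = np.full(slope.shape, np.nan)
    with np.errstate(invalid="ignore"):
        keep = h > 0.5
        flip = h < 0.5
    out[keep] = slope[keep]
    out[flip] = -slope[flip]
    return out


def forecast_dynamics(
    hurst_ndvi: HurstMap,
    hurst_cv: HurstMap,
    current: DegradationMap,
) -> ForecastMap:
    """Superimpose Hurst persistence on current trends to forecast dynamics.

    The forecast NDVI / CV slope signs follow the persistence rule per
    quantity; the forecast degradation level re-applies the level
    classification with the same NDVI value; the transition class compares
    current vs forecast membership of the degraded set.  Indeterminate
    wherever either H equals 0.5 or is missing, or the current level is
    undefined.
    """
    shapes = {hurst_ndvi.h.shape, hurst_cv.h.shape, current.ndvi_slope.shape}
    if len(shapes) != 1:
        raise ValueError(f"misaligned inputs: shapes {sorted(shapes)}")
    f_ndvi = _future_slope(current.ndvi_slope, hurst_ndvi.h)
    f_cv = _future_slope(current.cv_slope, hurst_cv.h)
    forecast_level = classify_degradation(f_ndvi, f_cv, current.ndvi_value)

    transition = np.full(current.level.shape, "", dtype=object)
    defined = (current.level != "") & (current.level != "Stable")
    indet = defined & ((forecast_level == "") | np.isnan(f_ndvi) | np.isnan(f_cv))
    cur_deg = np.isin(current.level, list(DEGRADED_LEVELS))
    fut_deg = np.isin(forecast_level, list(DEGRADED_LEVELS))
    ok = defined & ~indet
    transition[ok & ~cur_deg & ~fut_deg] = "continuous improvement"
    transition[ok & cur_deg & ~fut_deg] = "degradation to improvement"
    transition[ok & ~cur_deg & fut_deg] = "improvement to degradation"
    transition[ok & cur_deg & fut_deg] = "continuous degradation"
    transition[indet] = "indeterminate"
    return ForecastMap(forecast_level=forecast_level, transition=transition)
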
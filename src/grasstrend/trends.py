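"""Per-pixel trend machinery: Sen's slope, Mann-Kendall, windowed statistics.

The trend estimator throughout the mapping stages is the Theil-Sen median
slope, with significance from the two-sided Mann-Kendall test (normal
approximation with continuity and tie correction).  Spatial heterogeneity is
measured per year as the coefficient of variation of NDVI inside a 3x3
moving window (sample standard deviation over the nine cells divided by
their mean); its year-to-year trend is then analyzed with the same Sen/M-K
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .grid import GridStack

__all__ = [
    "sen_slope",
    "mann_kendall",
    "window_cv",
    "window_median",
    "window_stack",
    "trend_map",
    "correlation_map",
    "TrendMap",
]


def sen_slope(series: np.ndarray, years: np.ndarray | None = None) -> float:
    """Theil-Sen estimator: median of all pairwise slopes (a_j - a_i)/(t_j - t_i).

    NaNs are dropped; fewer than two valid points yields NaN.
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x), dtype=float) if years is None else np.asarray(years, dtype=float)
    ok = ~np.isnan(x)
    x, t = x[ok], t[ok]
    n = len(x)
    if n < 2:
        return float("nan")
    i, j = np.triu_indices(n, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def _mk_var(x: np.ndarray) -> float:
    """Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 with tie groups t."""
    n = len(x)
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    correction = np.sum(ties * (ties - 1) * (2 * ties + 5)) if len(ties) else 0.0
    return (n * (n - 1) * (2 * n + 5) - correction) / 18.0


def mann_kendall(series: np.ndarray) -> tuple[int, float, float]:
    """Mann-Kendall trend test.

    Returns ``(S, Z_c, p)`` where S is the sum of pairwise signs, Z_c the
    continuity-corrected standard normal deviate ((S-1)/sqrt(Var) for S>0,
    0 for S=0, (S+1)/sqrt(Var) for S<0) and p the two-sided p-value.
    Requires at least 4 valid points; otherwise returns (0, nan, nan).
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 4:
        return 0, float("nan"), float("nan")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(x[j] - x[i]).sum())
    var = _mk_var(x)
    if s == 0 or var <= 0:
        return s, 0.0, 1.0
    z = (s - 1) / np.sqrt(var) if s > 0 else (s + 1) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(p)


# ---------------------------------------------------------------------------
# Moving-window statistics
# ---------------------------------------------------------------------------

def _window_view(band: np.ndarray, size: int) -> np.ndarray:
    return sliding_window_view(band, (size, size)).reshape(
        band.shape[0] - size + 1, band.shape[1] - size + 1, size * size
    )


def _window_apply(band: np.ndarray, size: int, fn) -> np.ndarray:
    """Apply fn over complete windows; incomplete/edge/nodata windows -> NaN."""
    band = np.asarray(band, dtype=float)
    nr, nc = band.shape
    out = np.full((nr, nc), np.nan)
    if nr < size or nc < size:
        return out
    win = _window_view(band, size)
    vals = fn(win)
    vals[np.isnan(win).any(axis=-1)] = np.nan
    h = size // 2
    out[h : nr - h, h : nc - h] = vals
    return out


def window_cv(band: np.ndarray, size: int = 3) -> np.ndarray:
    """Per-pixel spatial coefficient of variation over a size x size window.

    CV = sample standard deviation (n-1) / mean of the window values, NaN
    wherever the window is incomplete, contains nodata, or has mean <= 0.
    """

    def cv(win: np.ndarray) -> np.ndarray:
        mean = win.mean(axis=-1)
        sd = win.std(axis=-1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sd / mean
        out[~(mean > 0)] = np.nan
        return out

    return _window_apply(band, size, cv)


def window_median(band: np.ndarray, size: int = 3) -> np.ndarray:
    """Median over a size x size window; same nodata policy as window_cv
    except the window mean may be any value."""
    return _window_apply(band, size, lambda w: np.median(w, axis=-1))


def window_stack(stack: GridStack, statistic: str = "cv", size: int = 3) -> GridStack:
    """Apply window_cv or window_median to every year of a stack."""
    fn = {"cv": window_cv, "median": window_median}[statistic]
    out = np.stack([fn(stack.values[b], size) for b in range(stack.n_years)])
    res = stack.copy(values=out)
    res.variable = f"{statistic}_{stack.variable}"
    if statistic == "cv":
        res.units = ""
    return res


# ---------------------------------------------------------------------------
# Trend and correlation maps
# ---------------------------------------------------------------------------

@dataclass
class TrendMap:
    """Per-pixel Sen slope and Mann-Kendall significance for a stack."""

    slope: np.ndarray        # variable units per year
    s_statistic: np.ndarray  # integer S (0 where undefined)
    z: np.ndarray
    p_value: np.ndarray
    alpha: float
    variable: str = ""

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_value < self.alpha


def trend_map(stack: GridStack, alpha: float = 0.05) -> TrendMap:
    """Sen slope + M-K test at every pixel with >= 4 valid years."""
    if stack.n_years < 4:
        raise ValueError("trend_map needs at least 4 years")
    vals = stack.values
    years = stack.years.astype(float)
    nr, nc = stack.shape
    slope = np.full((nr, nc), np.nan)
    s_stat = np.zeros((nr, nc), dtype=int)
    z = np.full((nr, nc), np.nan)
    p = np.full((nr, nc), np.nan)

    n = stack.n_years
    i, j = np.triu_indices(n, k=1)
    flat = vals.reshape(n, -1)
    valid_all = ~np.isnan(flat).any(axis=0)

    # fast path: pixels with complete series, fully vectorized
    idx = np.flatnonzero(valid_all)
    if idx.size:
        x = flat[:, idx]                             # (n, m)
        diffs = x[j] - x[i]                          # (pairs, m)
        dt = (years[j] - years[i])[:, None]
        slope.ravel()[idx] = np.median(diffs / dt, axis=0)
        s = np.sign(diffs).sum(axis=0)
        s_stat.ravel()[idx] = s.astype(int)
        var = np.array([_mk_var(x[:, k]) for k in range(x.shape[1])])
        zz = np.zeros_like(s)
        pos, neg = s > 0, s < 0
        with np.errstate(invalid="ignore", divide="ignore"):
            zz[pos] = (s[pos] - 1) / np.sqrt(var[pos])
            zz[neg] = (s[neg] + 1) / np.sqrt(var[neg])
        zz[var <= 0] = 0.0
        z.ravel()[idx] = zz
        pp = 2.0 * stats.norm.sf(np.abs(zz))
        pp[s == 0] = 1.0
        p.ravel()[idx] = pp

    # slow path: gappy pixels
    gappy = np.flatnonzero(~valid_all & ((~np.isnan(flat)).sum(axis=0) >= 4))
    for k in gappy:
        series = flat[:, k]
        ok = ~np.isnan(series)
        if ok.sum() < 4:
            continue
        slope.ravel()[k] = sen_slope(series, years)
        s_k, z_k, p_k = mann_kendall(series)
        s_stat.ravel()[k] = s_k
        z.ravel()[k] = z_k
        p.ravel()[k] = p_k

    return TrendMap(slope=slope, s_statistic=s_stat, z=z, p_value=p,
                    alpha=alpha, variable=stack.variable)


def correlation_map(a: GridStack, b: GridStack) -> np.ndarray:
    """Per-pixel Pearson correlation between two aligned stacks.

    NaN where either series is constant or contains nodata.
    """
    if a.n_years != b.n_years or not np.array_equal(a.years, b.years):
        raise ValueError("stacks must share the same years")
    a.require_same_grid(b)
    x = a.values - np.nanmean(a.values, axis=0)
    y = b.values - np.nanmean(b.values, axis=0)
    num = np.nansum(x * y, axis=0)
    den = np.sqrt(np.nansum(x * x, axis=0) * np.nansum(y * y, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    r[a.nodata_mask | b.nodata_mask] = np.nan
    return r
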
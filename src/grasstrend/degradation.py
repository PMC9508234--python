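"""Degradation/restoration levels and hot-plot detection.

Each pixel is classified from the signs of its NDVI and CV_NDVI Sen slopes
plus its mean NDVI level (0.2 separates substantive vegetation cover from
near-bare ground):

===========  ==========  ============  =====================
NDVI slope   CV slope    NDVI value    level
===========  ==========  ============  =====================
> 0          < 0                       Improving
> 0          > 0         < 0.2         Regrowing
> 0          > 0         >= 0.2        Slight degradation
< 0          > 0                       Moderate degradation
< 0          < 0         >= 0.2        Severe degradation
< 0          < 0         < 0.2         Desertification
===========  ==========  ============  =====================

An exactly zero slope (either one) is classed Stable and excluded from the
degraded/restored totals.  Hot plots — spatial clusters of degradation
intensity inside the degraded region — are found with Anselin's Local
Moran's I under queen contiguity with conditional-permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "DEGRADED_LEVELS",
    "RESTORED_LEVELS",
    "classify_degradation",
    "DegradationMap",
    "degradation_map",
    "local_morans_i",
    "hot_plots",
    "HotPlotMap",
]

#: integer codes for the degradation levels (0 reserved for nodata)
LEVELS = {
    1: "Improving",
    2: "Regrowing",
    3: "Slight degradation",
    4: "Moderate degradation",
    5: "Severe degradation",
    6: "Desertification",
    7: "Stable",
}
LEVEL_CODES = {v: k for k, v in LEVELS.items()}
DEGRADED_LEVELS = frozenset(
    ["Slight degradation", "Moderate degradation", "Severe degradation", "Desertification"]
)
RESTORED_LEVELS = frozenset(["Improving", "Regrowing"])

NDVI_COVER_THRESHOLD = 0.2  # NDVI below this indicates near-bare ground


def classify_degradation(
    ndvi_slope: np.ndarray | float,
    cv_slope: np.ndarray | float,
    ndvi_value: np.ndarray | float,
) -> np.ndarray | str:
    """Map (NDVI slope, CV slope, NDVI level) to a degradation level.

    Vectorized; scalar inputs return a scalar string.  The 0.2 NDVI
    threshold is closed on the high side (exactly 0.2 counts as covered).
    NaN in any input yields the empty string (nodata).
    """
    ns = np.asarray(ndvi_slope, dtype=float)
    cs = np.asarray(cv_slope, dtype=float)
    nv = np.asarray(ndvi_value, dtype=float)
    scalar = ns.ndim == 0
    ns, cs, nv = np.atleast_1d(ns), np.atleast_1d(cs), np.atleast_1d(nv)

    low = nv < NDVI_COVER_THRESHOLD
    out = np.select(
        [
            np.isnan(ns) | np.isnan(cs) | np.isnan(nv),
            (ns == 0) | (cs == 0),
            (ns > 0) & (cs < 0),
            (ns > 0) & (cs > 0) & low,
            (ns > 0) & (cs > 0) & ~low,
            (ns < 0) & (cs > 0),
            (ns < 0) & (cs < 0) & ~low,
            (ns < 0) & (cs < 0) & low,
        ],
        [
            "",
            "Stable",
            "Improving",
            "Regrowing",
            "Slight degradation",
            "Moderate degradation",
            "Severe degradation",
            "Desertification",
        ],
        default="",
    )
    return out.item() if scalar else out


@dataclass
class DegradationMap:
    """Per-pixel level plus the three inputs it was derived from."""

    level: np.ndarray        # object array of level names ("" = nodata)
    ndvi_slope: np.ndarray
    cv_slope: np.ndarray
    ndvi_value: np.ndarray

    @property
    def codes(self) -> np.ndarray:
        out = np.zeros(self.level.shape, dtype=np.int16)
        for name, code in LEVEL_CODES.items():
            out[self.level == name] = code
        return out

    @property
    def degraded(self) -> np.ndarray:
        return np.isin(self.level, list(DEGRADED_LEVELS))

    @property
    def restored(self) -> np.ndarray:
        return np.isin(self.level, list(RESTORED_LEVELS))

    def area_summary(self, cell_area: float = 1.0) -> pd.DataFrame:
        """Pixel count, area and % of analyzed area per level."""
        analyzed = self.level != ""
        total = int(analyzed.sum())
        rows = []
        for code, name in LEVELS.items():
            n = int((self.level == name).sum())
            rows.append({
                "level": name, "code": code, "pixels": n,
                "area": n * cell_area,
                "percent": 100.0 * n / total if total else np.nan,
            })
        return pd.DataFrame(rows)


def degradation_map(ndvi_trend, cv_trend, ndvi_value: np.ndarray) -> DegradationMap:
    """Classify every pixel from NDVI / CV trend maps and the mean NDVI level.

    ``ndvi_trend`` and ``cv_trend`` are :class:`~grasstrend.trends.TrendMap`
    objects (their ``slope`` fields are used); ``ndvi_value`` is the study-
    period mean of the per-year window-median NDVI.
    """
    level = classify_degradation(ndvi_trend.slope, cv_trend.slope, ndvi_value)
    return DegradationMap(level=level, ndvi_slope=ndvi_trend.slope,
                          cv_slope=cv_trend.slope, ndvi_value=ndvi_value)


# ---------------------------------------------------------------------------
# Local Moran's I
# ---------------------------------------------------------------------------

def _queen_neighbors(mask: np.ndarray) -> list[np.ndarray]:
    """For each True cell (in flat order of True cells), indices of its
    queen-contiguous True neighbors, as positions into the True-cell list."""
    nr, nc = mask.shape
    pos = -np.ones(mask.shape, dtype=int)
    cells = np.argwhere(mask)
    pos[mask] = np.arange(len(cells))
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    neighbors = []
    for r, c in cells:
        idx = []
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc]:
                idx.append(pos[rr, cc])
        neighbors.append(np.array(idx, dtype=int))
    return neighbors


@dataclass
class HotPlotMap:
    """Local Moran's I results over the analyzed (degraded) region."""

    local_i: np.ndarray     # NaN outside the analyzed region
    p_value: np.ndarray
    cluster: np.ndarray     # HH | LL | HL | LH | ns | "" (outside)
    alpha: float

    @property
    def clustered_fraction(self) -> float:
        inside = self.cluster != ""
        if not inside.any():
            return float("nan")
        sig = np.isin(self.cluster, ["HH", "LL", "HL", "LH"])
        return float(sig.sum() / inside.sum())


def local_morans_i(
    values: np.ndarray,
    mask: np.ndarray,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local Moran's I with row-standardized queen weights on a raster subset.

    Returns ``(I, p, quadrant)`` full-grid arrays; ``quadrant`` is "HH",
    "LL", "HL", "LH" by the sign of the deviation and of the spatial lag
    (no significance applied here), "" outside the mask or for isolated
    cells.  p-values are one-sided conditional-permutation pseudo
    p-values: each cell's neighbor values are redrawn from the remaining
    cells, and p = (more-extreme + 1) / (n_permutations + 1) on the tail
    matching the observed statistic's sign.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=float)[mask]
    n = len(x)
    I = np.full(mask.shape, np.nan)
    P = np.full(mask.shape, np.nan)
    Q = np.full(mask.shape, "", dtype=object)
    if n < 2:
        return I, P, Q
    z = (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else np.zeros(n)
    neighbors = _queen_neighbors(mask)

    obs_i = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    quad = np.full(n, "", dtype=object)
    for k, nbrs in enumerate(neighbors):
        if len(nbrs) == 0:
            continue
        lag = z[nbrs].mean()
        obs_i[k] = z[k] * lag
        quad[k] = ("H" if z[k] > 0 else "L") + ("H" if lag > 0 else "L")
        # conditional permutation: draw neighbor values from the other cells
        others = np.delete(z, k)
        draw = rng.choice(len(others), size=(n_permutations, len(nbrs)), replace=True)
        sim = z[k] * others[draw].mean(axis=1)
        if obs_i[k] >= 0:
            extreme = (sim >= obs_i[k]).sum()
        else:
            extreme = (sim <= obs_i[k]).sum()
        pvals[k] = (extreme + 1) / (n_permutations + 1)

    I[mask], P[mask], Q[mask] = obs_i, pvals, quad
    return I, P, Q


def hot_plots(
    degradation: DegradationMap,
    intensity: np.ndarray | None = None,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> HotPlotMap:
    """Detect clusters of degradation intensity inside the degraded region.

    ``intensity`` defaults to the NDVI Sen slope (strongly negative slope =
    intense degradation).  Requires at least 10 degraded pixels.
    """
    region = degradation.degraded
    if intensity is None:
        intensity = degradation.ndvi_slope
    region = region & ~np.isnan(np.asarray(intensity, dtype=float))
    if region.sum() < 10:
        raise ValueError(
            f"hot-plot analysis needs >= 10 degraded pixels, found {int(region.sum())}"
        )
    I, P, Q = local_morans_i(intensity, region, n_permutations=n_permutations, seed=seed)
    cluster = np.full(region.shape, "", dtype=object)
    inside = region
    with np.errstate(invalid="ignore"):
        sig = inside & (P < alpha)
    cluster[inside] = "ns"
    cluster[sig] = Q[sig]
    return HotPlotMap(local_i=I, p_value=P, cluster=cluster, alpha=alpha)
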
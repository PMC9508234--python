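"""Synthetic scenes with known per-pixel drivers, plus exact fGn series.

Every downstream stage of the pipeline is exercised against scenes generated
here, because the generating process *is* the model the attribution method
assumes: per pixel, NDVI is a linear response to climate (a*T + b*P + c*S + d)
plus an additive linear human-activity trend plus Gaussian noise.  The
generator therefore knows, for every pixel, the true regression coefficients,
the true climate/human driver label, and the true scenario, which the
recovery tests compare against.

Climate fields are spatially smooth (Gaussian-filtered white noise added to a
mean surface) with a prescribed linear trend per year and iid observation
noise.  Fractional Gaussian noise for the Hurst estimator tests is generated
by circulant (Davies-Harte) embedding, which realizes the exact fGn
autocovariance and so serves as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridStack, GridTransform

__all__ = [
    "ClimateSpec",
    "RegionSpec",
    "SceneConfig",
    "SyntheticTruth",
    "generate_climate",
    "generate_ndvi",
    "generate_scene",
    "generate_fgn",
    "fgn_autocorr",
]

@dataclass(frozen=True)
class ClimateSpec:
    """Generating parameters for one climate variable.

    ``mean``: spatial mean level (variable units); ``trend``: linear change
    per year; ``noise_sd``: sd of the interannual Gaussian anomaly (one draw
    per year, spatially uniform — weather anomalies are regional at scene
    scale); ``pixel_noise_sd``: optional additional iid per-(year, pixel)
    noise; ``spatial_sd`` and ``smooth_len``: amplitude and Gaussian length
    scale (pixels) of the smooth time-constant spatial field.
    """

    mean: float
    trend: float = 0.0
    noise_sd: float = 0.0
    pixel_noise_sd: float = 0.0
    spatial_sd: float = 0.0
    smooth_len: float = 5.0
    units: str = ""


@dataclass(frozen=True)
class RegionSpec:
    """Generating parameters for one rectangular region of the scene.

    ``coeffs`` maps climate variable name -> response coefficient (the a, b,
    c of the linear climate response); ``intercept`` is the constant d;
    ``human_trend`` is the additive human-activity trend in NDVI/year
    (0 = untouched, negative = degradation pressure);
    ``human_patchiness`` scales a fixed per-pixel multiplier on the human
    trend (h_p = h * (1 + patchiness * u_p), u_p ~ N(0,1) iid in space,
    constant in time) — patchy pressure raises spatial heterogeneity over
    time, which is how degradation shows up in the windowed CV.
    """

    row_slice: tuple[int, int]
    col_slice: tuple[int, int]
    coeffs: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.3
    human_trend: float = 0.0
    human_patchiness: float = 0.0


def _default_climate() -> dict[str, ClimateSpec]:
    # Alpine-meadow setting: modest warming/wetting trends with strong
    # interannual anomalies (the anomalies, not the trends, are what let the
    # climate->NDVI regression identify the response); sunshine, wind and
    # radiation are decoys for the variable-selection stage.
    return {
        "temperature": ClimateSpec(mean=-1.0, trend=0.04, noise_sd=0.45,
                                   pixel_noise_sd=0.12, spatial_sd=0.8,
                                   smooth_len=6, units="degC"),
        "precipitation": ClimateSpec(mean=420.0, trend=2.0, noise_sd=28.0,
                                     pixel_noise_sd=9.0, spatial_sd=40.0,
                                     smooth_len=8, units="mm"),
        "sunshine": ClimateSpec(mean=2800.0, trend=0.0, noise_sd=60.0,
                                pixel_noise_sd=18.0, spatial_sd=80.0,
                                smooth_len=8, units="h"),
        "wind": ClimateSpec(mean=2.2, trend=0.0, noise_sd=0.25,
                            pixel_noise_sd=0.08, spatial_sd=0.3,
                            smooth_len=5, units="m/s"),
        "radiation": ClimateSpec(mean=6200.0, trend=0.0, noise_sd=120.0,
                                 pixel_noise_sd=45.0, spatial_sd=150.0,
                                 smooth_len=5, units="MJ/m2"),
    }


#: NDVI response used by the default regions: greening under warming and
#: wetting (slope_C = 0.1*0.04 + 0.002*2.0 = 0.008 NDVI/yr)
_GREENING = {"temperature": 0.1, "precipitation": 0.002}
#: browning response (wet-meadow loss under warming): slope_C = -0.008
_BROWNING = {"temperature": -0.1, "precipitation": -0.002}


def _default_regions(n_rows: int, n_cols: int) -> list[RegionSpec]:
    """Quadrant layout covering four driver/dynamics regimes.

    NDVI responds to temperature and precipitation only (sunshine, wind and
    radiation are decoys).  Every quadrant carries both a climate and a
    human component with |slope| >= 0.003/yr so all attribution signs are
    well separated from zero; patchy human pressure drives the CV upward in
    the degrading quadrants.
    """
    rm, cm = n_rows // 2, n_cols // 2
    return [
        # improvement, both drivers: climate greening + uniform restoration
        RegionSpec((0, rm), (0, cm), coeffs=dict(_GREENING), intercept=0.35,
                   human_trend=0.0045),
        # slight degradation / regrowing: greening with patchy human pressure
        # (mean NDVI rises, spatial heterogeneity rises faster)
        RegionSpec((0, rm), (cm, n_cols), coeffs=dict(_GREENING), intercept=0.40,
                   human_trend=0.0045, human_patchiness=1.2),
        # moderate degradation, human-driven: overgrazing overwhelms greening
        RegionSpec((rm, n_rows), (0, cm), coeffs=dict(_GREENING), intercept=0.55,
                   human_trend=-0.014, human_patchiness=0.35),
        # moderate degradation, climate-driven: browning response with
        # partially compensating restoration effort
        RegionSpec((rm, n_rows), (cm, n_cols), coeffs=dict(_BROWNING), intercept=0.55,
                   human_trend=0.003),
    ]


@dataclass
class SceneConfig:
    """Full description of a synthetic scene; seed fixes every random draw."""

    n_years: int = 20
    n_rows: int = 40
    n_cols: int = 40
    start_year: int = 2000
    climate: dict[str, ClimateSpec] = field(default_factory=_default_climate)
    regions: list[RegionSpec] | None = None
    ndvi_noise_sd: float = 0.02
    ndvi_texture_sd: float = 0.08
    clip: tuple[float, float] = (-0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10 for trend and regression stages")
        if self.ndvi_noise_sd < 0 or any(c.noise_sd < 0 for c in self.climate.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.regions is None:
            self.regions = _default_regions(self.n_rows, self.n_cols)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class SyntheticTruth:
    """Per-pixel generating parameters and derived truth labels.

    ``ndvi_driver`` is the generator label (which trend components are
    switched on).  The scenario and level labels are derived from the
    *identifiable* decomposition: the share of a linear human trend that is
    collinear in-sample with the climate series cannot be attributed by any
    residual method, so true component slopes are defined via the exact OLS
    projection of the noise-free signal onto the true climate predictors —
    deterministic given config and seed, and independent of the estimation
    pipeline.
    """

    coeffs: dict[str, np.ndarray]      # variable -> (row, col) response coefficient
    intercept: np.ndarray
    human_trend: np.ndarray            # nominal human trend h (NDVI/year)
    human_trend_pixel: np.ndarray      # effective per-pixel h_p incl. patchiness
    climate_slope: np.ndarray          # NDVI/year implied by climate trends
    ndvi_driver: np.ndarray            # object array: climate | human | both | none
    scenario: np.ndarray               # int 1..12 (0 where undefined)
    scenario_label: np.ndarray         # e.g. "BDI" ("" where undefined)
    level: np.ndarray                  # degradation level name ("" where undefined)

    def to_frame(self) -> pd.DataFrame:
        nr, nc = self.intercept.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        data = {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "intercept": self.intercept.ravel(),
            "human_trend": self.human_trend.ravel(),
            "human_trend_pixel": self.human_trend_pixel.ravel(),
            "climate_slope": self.climate_slope.ravel(),
            "ndvi_driver": self.ndvi_driver.ravel(),
            "scenario": self.scenario.ravel(),
            "scenario_label": self.scenario_label.ravel(),
            "level": self.level.ravel(),
        }
        for name, arr in self.coeffs.items():
            data[f"coef_{name}"] = arr.ravel()
        return pd.DataFrame(data)


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


_CLIMATE_TAGS = {"temperature": 11, "precipitation": 12, "sunshine": 13,
                 "wind": 14, "radiation": 15}


def generate_climate(config: SceneConfig, variable: str) -> GridStack:
    """One climate stack: smooth spatial mean + trend*(year-year0) + iid noise."""
    spec = config.climate[variable]
    tag = _CLIMATE_TAGS.get(variable, 10 + sum(map(ord, variable)) % 1000)
    rng = _stream_rng(config.seed, tag)
    nr, nc, ny = config.n_rows, config.n_cols, config.n_years

    base = np.full((nr, nc), spec.mean)
    if spec.spatial_sd > 0:
        white = rng.standard_normal((nr, nc))
        smooth = ndimage.gaussian_filter(white, spec.smooth_len, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            base = base + spec.spatial_sd * smooth / sd
    t = np.arange(ny)[:, None, None]
    values = base[None] + spec.trend * t
    if spec.noise_sd > 0:
        # interannual weather anomaly: one draw per year, spatially uniform,
        # detrended in-sample so the realized trend equals `trend` exactly
        # (the prescribed trend is the condition the scene asserts)
        anom = spec.noise_sd * rng.standard_normal(ny)
        tt = np.arange(ny, dtype=float)
        anom = anom - np.polyval(np.polyfit(tt, anom, 1), tt)
        values = values + anom[:, None, None]
    if spec.pixel_noise_sd > 0:
        values = values + spec.pixel_noise_sd * rng.standard_normal((ny, nr, nc))
    return GridStack(values=values, years=config.years, variable=variable,
                     units=spec.units, transform=GridTransform(), crs_id="synthetic")


def _region_fields(
    config: SceneConfig,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel coefficient / intercept / human-trend / patchiness fields."""
    nr, nc = config.n_rows, config.n_cols
    coeffs = {name: np.zeros((nr, nc)) for name in config.climate}
    intercept = np.zeros((nr, nc))
    human = np.zeros((nr, nc))
    patchiness = np.zeros((nr, nc))
    for reg in config.regions:
        r0, r1 = reg.row_slice
        c0, c1 = reg.col_slice
        for name, c in reg.coeffs.items():
            coeffs[name][r0:r1, c0:c1] = c
        intercept[r0:r1, c0:c1] = reg.intercept
        human[r0:r1, c0:c1] = reg.human_trend
        patchiness[r0:r1, c0:c1] = reg.human_patchiness
    return coeffs, intercept, human, patchiness


def generate_ndvi(
    config: SceneConfig, climate: dict[str, GridStack]
) -> tuple[GridStack, SyntheticTruth]:
    """NDVI = sum_v coef_v * climate_v + d + h_p*(year-year0) + noise.

    ``h_p = human_trend * (1 + patchiness * u_p)`` with a fixed iid standard
    normal field u_p, so patchy human pressure raises spatial heterogeneity
    over time.  Values are clipped to ``config.clip``; clipping breaks exact
    additivity, so the number of clipped cells is recorded on the returned
    stack as ``stack.n_clipped`` and kept near zero at default settings.

    Generator driver labels per pixel: ``climate`` if the climate-implied
    NDVI trend is nonzero and the human trend is zero, ``human`` for the
    reverse, ``both`` when both act, ``none`` when neither does.  Scenario
    and level truth labels are derived from the identifiable decomposition
    (see :class:`SyntheticTruth`).
    """
    stacks = list(climate.values())
    for s in stacks[1:]:
        stacks[0].require_same_grid(s)
    coeffs, intercept, human, patchiness = _region_fields(config)
    ny, nr, nc = config.n_years, config.n_rows, config.n_cols
    t = np.arange(ny)[:, None, None]

    # patchiness multipliers are clipped at +-2 sd: keeps heterogeneity
    # bounded so trend tails rarely push NDVI into the physical clip range
    u = np.clip(_stream_rng(config.seed, 77).standard_normal((nr, nc)), -2.0, 2.0)
    human_px = human * (1.0 + patchiness * u)
    # static micro-site heterogeneity (soil depth, micro-topography): gives
    # the 3x3 window a stable spatial texture, the carrier of the CV signal
    texture = config.ndvi_texture_sd * _stream_rng(config.seed, 78).standard_normal((nr, nc))

    # the response acts on climate anomalies about each variable's mean, so
    # the region intercept is the baseline NDVI level (the constant d of the
    # pixel regression absorbs -sum(coef * mean))
    signal = np.broadcast_to((intercept + texture)[None], (ny, nr, nc)).copy()
    climate_slope = np.zeros((nr, nc))
    for name, stack in climate.items():
        signal += coeffs[name][None] * (stack.values - config.climate[name].mean)
        climate_slope += coeffs[name] * config.climate[name].trend
    signal += human_px[None] * t

    # saturation is part of the generating process: the noise-free signal is
    # clipped to the physical range (NDVI saturates at dense cover), so all
    # truth labels are computed from the same saturated series the pipeline
    # observes; observation noise is added on top and re-clipped
    lo, hi = config.clip
    n_clipped = int(((signal < lo) | (signal > hi)).sum())
    signal = np.clip(signal, lo, hi)

    rng = _stream_rng(config.seed, 99)
    values = signal.copy()
    if config.ndvi_noise_sd > 0:
        values = np.clip(
            values + config.ndvi_noise_sd * rng.standard_normal(values.shape), lo, hi
        )

    ndvi = GridStack(values=values, years=config.years, variable="ndvi",
                     units="", transform=stacks[0].transform, crs_id=stacks[0].crs_id)
    ndvi.n_clipped = n_clipped

    has_climate = climate_slope != 0
    has_human = human != 0
    driver = np.full((nr, nc), "none", dtype=object)
    driver[has_climate & ~has_human] = "climate"
    driver[~has_climate & has_human] = "human"
    driver[has_climate & has_human] = "both"

    # effective regression constant: d = baseline - sum(coef * mean)
    d_eff = intercept.copy()
    for name in climate:
        d_eff -= coeffs[name] * config.climate[name].mean

    scenario, label, level = _truth_labels(config, climate, signal, coeffs)
    truth = SyntheticTruth(
        coeffs=coeffs, intercept=d_eff, human_trend=human,
        human_trend_pixel=human_px, climate_slope=climate_slope,
        ndvi_driver=driver, scenario=scenario, scenario_label=label, level=level,
    )
    return ndvi, truth


def _ols_slopes(values: np.ndarray) -> np.ndarray:
    """OLS slope against band index for a (year, row, col) array."""
    ny = values.shape[0]
    tc = np.arange(ny) - (ny - 1) / 2.0
    flat = values.reshape(ny, -1)
    out = np.einsum("t,tp->p", tc, np.nan_to_num(flat)) / (tc**2).sum()
    out[np.isnan(flat).any(axis=0)] = np.nan
    return out.reshape(values.shape[1:])


def _truth_labels(
    config: SceneConfig,
    climate: dict[str, GridStack],
    signal: np.ndarray,
    coeffs: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scenario/level truth from the identifiable decomposition.

    The true climate component is the per-pixel OLS projection of the
    noise-free signal onto the true predictor set (variables with a nonzero
    response anywhere) plus intercept; the human component is the remainder.
    Driver codes and scenarios follow the same classification tables the
    pipeline uses (the tables are definitional lookups, tested exactly).
    """
    from .degradation import classify_degradation
    from .restrend import classify_driver, classify_scenario, driver_code
    from .trends import window_cv, window_median

    ny, nr, nc = signal.shape
    predictors = [n for n, c in coeffs.items() if np.any(c != 0)]
    flat = signal.reshape(ny, -1)
    proj = np.empty_like(flat)
    if predictors:
        design = np.empty((ny, len(predictors) + 1, nr * nc))
        for k, name in enumerate(predictors):
            design[:, k, :] = climate[name].values.reshape(ny, -1)
        design[:, -1, :] = 1.0
        for p in range(nr * nc):
            beta, *_ = np.linalg.lstsq(design[:, :, p], flat[:, p], rcond=None)
            proj[:, p] = design[:, :, p] @ beta
    else:
        proj[:] = flat.mean(axis=0, keepdims=True)
    ndvi_c = proj.reshape(ny, nr, nc)
    ndvi_h = signal - ndvi_c

    cv_obs = np.stack([window_cv(signal[b]) for b in range(ny)])
    cv_c = np.stack([window_cv(ndvi_c[b]) for b in range(ny)])
    cv_h = cv_obs - cv_c
    med = np.stack([window_median(signal[b]) for b in range(ny)])

    s = {
        "n_obs": _ols_slopes(signal), "n_c": _ols_slopes(ndvi_c), "n_h": _ols_slopes(ndvi_h),
        "c_obs": _ols_slopes(cv_obs), "c_c": _ols_slopes(cv_c), "c_h": _ols_slopes(cv_h),
    }
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        level = classify_degradation(_ols_slopes(med), s["c_obs"], np.nanmean(med, axis=0))

    scenario = np.zeros((nr, nc), dtype=int)
    label = np.full((nr, nc), "", dtype=object)
    ok = ~np.isnan(s["n_obs"]) & ~np.isnan(s["c_obs"]) & (s["n_obs"] != 0) & (s["c_obs"] != 0)
    ok &= ~np.isnan(s["c_c"]) & ~np.isnan(s["c_h"])
    for r, c in np.argwhere(ok):
        try:
            nd, _, _ = classify_driver(s["n_obs"][r, c], s["n_c"][r, c], s["n_h"][r, c])
            cd, _, _ = classify_driver(s["c_obs"][r, c], s["c_c"][r, c], s["c_h"][r, c])
        except ValueError:
            continue
        ncode = driver_code(nd, s["n_obs"][r, c] > 0, "ndvi")
        ccode = driver_code(cd, s["c_obs"][r, c] > 0, "cv")
        sid, lab = classify_scenario(ncode, ccode)
        scenario[r, c] = sid
        label[r, c] = lab
    return scenario, label, level


def generate_scene(config: SceneConfig) -> tuple[GridStack, dict[str, GridStack], SyntheticTruth]:
    """Generate all climate stacks and the NDVI stack for one scene."""
    climate = {name: generate_climate(config, name) for name in config.climate}
    ndvi, truth = generate_ndvi(config, climate)
    return ndvi, climate, truth


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (exact circulant embedding)
# ---------------------------------------------------------------------------

def fgn_autocorr(hurst: float, lag: int) -> float:
    """Exact fGn autocorrelation rho(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2."""
    k = abs(lag)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + abs(k - 1) ** h2)


def generate_fgn(hurst: float, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise by circulant embedding.

    ``n`` must be a power of two >= 64 (keeps the embedding eigenvalues
    provably nonnegative for all H in (0, 1) and the FFT fast).  Unit
    variance, zero mean.  At H = 0.5 this reduces to white noise.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 64 or (n & (n - 1)) != 0:
        raise ValueError(f"n must be a power of 2 >= 64, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = np.arange(n + 1)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2.0 * hurst)
                   + np.abs(k - 1) ** (2.0 * hurst))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])          # length 2n
    eig = np.fft.fft(circ).real
    eig = np.maximum(eig, 0.0)                              # clip fp negatives ~ -1e-15

    m = 2 * n
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(eig / m) * w)
    return f.real[:n]
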
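"""End-to-end orchestration: one config in, a directory of audited maps out.

Every stage output is materialized to disk (GeoTIFF-style stacks, coded maps
with sidecar code tables, summary CSVs) so any stage can be re-run and
audited in isolation; a JSON manifest records the config, the product list
and a checksum per product, making runs diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import degradation as deg
from . import hurst as hx
from . import restrend as rt
from . import trends as tr
from .grid import GridStack, Mask, apply_mask, read_mask, read_stack, write_stack
from .synthetic import ClimateSpec, RegionSpec, SceneConfig, generate_scene

log = logging.getLogger("grasstrend")

__all__ = ["RunConfig", "run_pipeline", "summarize_areas", "load_config"]


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run.

    Exactly one of ``ndvi_path`` (with ``climate_paths``) or ``scene`` must
    be provided; a run is reproducible from the config and seed alone.
    """

    output_dir: str = "grasstrend_run"
    seed: int = 0
    # inputs: either real rasters ...
    ndvi_path: str | None = None
    climate_paths: dict[str, str] = field(default_factory=dict)
    mask_path: str | None = None
    mask_buffer: int = 1
    # ... or a synthetic scene
    scene: SceneConfig | None = None
    # analysis settings
    alpha: float = 0.05
    window: int = 3
    slope_mode: str = "ols"
    selection_seed: int | None = None
    rf_trees: int = 500
    rf_max_rows: int = 100_000
    hot_permutations: int = 999
    hurst_correction: bool = False

    def validate(self) -> None:
        if self.scene is None and self.ndvi_path is None:
            raise ValueError(
                "config must provide either 'scene' (synthetic) or 'ndvi_path' + "
                "'climate_paths' (raster inputs); both are missing"
            )
        if self.scene is None and not self.climate_paths:
            raise ValueError("'climate_paths' is required when running from rasters")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file (scene/climate blocks nested)."""
    raw = yaml.safe_load(Path(path).read_text())
    scene = None
    if "scene" in raw and raw["scene"] is not None:
        s = dict(raw.pop("scene"))
        climate = {
            name: ClimateSpec(**spec) for name, spec in s.pop("climate", {}).items()
        } or None
        regions = [RegionSpec(**r) for r in s.pop("regions", [])] or None
        kwargs = dict(s)
        if climate:
            kwargs["climate"] = climate
        if regions:
            kwargs["regions"] = [
                RegionSpec(tuple(r.row_slice), tuple(r.col_slice), r.coeffs,
                           r.intercept, r.human_trend, r.human_patchiness)
                for r in regions
            ]
        scene = SceneConfig(**kwargs)
    cfg = RunConfig(scene=scene, **raw)
    return cfg


def summarize_areas(codes: np.ndarray, code_table: dict[int, str],
                    cell_area: float = 1.0) -> pd.DataFrame:
    """Per-class pixel count, area and percentage of the analyzed area.

    ``codes`` is an integer map with 0 = nodata; unknown nonzero codes raise.
    Percentages sum to 100 up to rounding; an all-nodata map yields an empty
    table with a warning.
    """
    vals, counts = np.unique(codes[codes != 0], return_counts=True)
    unknown = [int(v) for v in vals if int(v) not in code_table]
    if unknown:
        raise ValueError(f"unknown class codes in map: {unknown}")
    total = counts.sum()
    if total == 0:
        log.warning("summarize_areas: map is entirely nodata")
        return pd.DataFrame(columns=["code", "label", "pixels", "area", "percent"])
    rows = [
        {"code": int(v), "label": code_table[int(v)], "pixels": int(n),
         "area": float(n * cell_area), "percent": float(100.0 * n / total)}
        for v, n in zip(vals, counts)
    ]
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_coded(path: Path, codes: np.ndarray, table: dict[int, str]) -> None:
    np.savetxt(path, codes, fmt="%d", delimiter=",")
    pd.DataFrame(
        [{"code": k, "label": v} for k, v in table.items()]
    ).to_csv(path.with_suffix(".codes.csv"), index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written).

    Stages: trend mapping -> degradation levels -> hot plots -> variable
    selection -> pixel regressions -> residual decomposition -> driver /
    scenario attribution -> Hurst -> forecast.  Any stage failure aborts
    with the stage name in the exception message.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    products: dict[str, Path] = {}
    stage = "inputs"
    try:
        if config.scene is not None:
            ndvi, climate, truth = generate_scene(config.scene)
            truth.to_frame().to_csv(out / "truth.csv", index=False)
            products["truth"] = out / "truth.csv"
        else:
            ndvi = read_stack(config.ndvi_path)
            climate = {name: read_stack(p) for name, p in config.climate_paths.items()}
        if config.mask_path:
            mask = read_mask(config.mask_path)
            ndvi = apply_mask(ndvi, mask, config.mask_buffer)
        write_stack(ndvi, out / "ndvi.tif")
        products["ndvi"] = out / "ndvi.tif"

        stage = "windowed statistics"
        cv = tr.window_stack(ndvi, "cv", config.window)
        med = tr.window_stack(ndvi, "median", config.window)
        write_stack(cv, out / "cv_ndvi.tif")
        products["cv_ndvi"] = out / "cv_ndvi.tif"

        stage = "trend mapping"
        ndvi_trend = tr.trend_map(med, config.alpha)
        cv_trend = tr.trend_map(cv, config.alpha)
        np.savetxt(out / "ndvi_slope.csv", ndvi_trend.slope, delimiter=",")
        np.savetxt(out / "cv_slope.csv", cv_trend.slope, delimiter=",")
        products["ndvi_slope"] = out / "ndvi_slope.csv"
        products["cv_slope"] = out / "cv_slope.csv"

        stage = "degradation classification"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ndvi_value = np.nanmean(med.values, axis=0)
        dmap = deg.degradation_map(ndvi_trend, cv_trend, ndvi_value)
        _write_coded(out / "degradation.csv", dmap.codes, deg.LEVELS)
        dmap.area_summary().to_csv(out / "degradation_areas.csv", index=False)
        products["degradation"] = out / "degradation.csv"
        products["degradation_areas"] = out / "degradation_areas.csv"

        stage = "hot plots"
        try:
            hmap = deg.hot_plots(dmap, n_permutations=config.hot_permutations,
                                 alpha=config.alpha, seed=config.seed)
            cl_codes = np.zeros(dmap.level.shape, dtype=int)
            cl_table = {1: "HH", 2: "LL", 3: "HL", 4: "LH", 5: "ns"}
            for code, lab in cl_table.items():
                cl_codes[hmap.cluster == lab] = code
            _write_coded(out / "hot_plots.csv", cl_codes, cl_table)
            products["hot_plots"] = out / "hot_plots.csv"
        except ValueError as err:
            log.warning("hot plots skipped: %s", err)

        stage = "variable selection"
        sel = rt.select_climate_variables(
            ndvi, climate,
            seed=config.selection_seed if config.selection_seed is not None else config.seed,
            n_trees=config.rf_trees, max_rows=config.rf_max_rows,
        )
        report = pd.DataFrame({
            "variable": sel.rf_importance.index,
            "rf_importance": sel.rf_importance.values,
            "stepwise_retained": [v in sel.stepwise_retained for v in sel.rf_importance.index],
            "selected": [v in sel.selected for v in sel.rf_importance.index],
        })
        report.to_csv(out / "selection_report.csv", index=False)
        products["selection_report"] = out / "selection_report.csv"
        if not sel.selected:
            raise RuntimeError("no climate variable survived selection")

        stage = "pixel regressions"
        regs = rt.fit_pixel_regressions(ndvi, climate, sel.selected)
        write_stack(regs.predicted, out / "ndvi_c.tif")
        products["ndvi_c"] = out / "ndvi_c.tif"

        stage = "residual decomposition"
        residuals = rt.decompose(ndvi, regs.predicted, config.window)
        write_stack(residuals.ndvi_h, out / "ndvi_h.tif")
        products["ndvi_h"] = out / "ndvi_h.tif"

        stage = "driver attribution"
        drivers, scenarios = rt.attribute(residuals, slope_mode=config.slope_mode)
        np.savetxt(out / "climate_contribution.csv", drivers.ndvi_climate_pct, delimiter=",")
        _write_coded(out / "scenarios.csv", scenarios.scenario,
                     {k: v[0] for k, v in rt.SCENARIO_LABELS.items()})
        scenarios.area_summary().to_csv(out / "scenario_areas.csv", index=False)
        products["climate_contribution"] = out / "climate_contribution.csv"
        products["scenarios"] = out / "scenarios.csv"
        products["scenario_areas"] = out / "scenario_areas.csv"

        stage = "hurst"
        h_ndvi = hx.hurst_map(med, correction=config.hurst_correction)
        h_cv = hx.hurst_map(cv, correction=config.hurst_correction)
        np.savetxt(out / "hurst_ndvi.csv", h_ndvi.h, delimiter=",")
        products["hurst_ndvi"] = out / "hurst_ndvi.csv"

        stage = "forecast"
        fmap = hx.forecast_dynamics(h_ndvi, h_cv, dmap)
        t_table = {i + 1: t for i, t in enumerate(hx.TRANSITIONS)}
        t_codes = np.zeros(fmap.transition.shape, dtype=int)
        for code, lab in t_table.items():
            t_codes[fmap.transition == lab] = code
        _write_coded(out / "forecast.csv", t_codes, t_table)
        fmap.area_summary().to_csv(out / "forecast_areas.csv", index=False)
        products["forecast"] = out / "forecast.csv"
        products["forecast_areas"] = out / "forecast_areas.csv"
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": _config_dict(config),
        "products": {k: str(v) for k, v in products.items()},
        "checksums": {k: _sha256(v) for k, v in products.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.scene is not None:
        d["scene"]["climate"] = {k: asdict(v) for k, v in config.scene.climate.items()}
        d["scene"]["regions"] = [asdict(r) for r in config.scene.regions]
    return d
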
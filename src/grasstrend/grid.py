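"""Annual raster stacks: data model, GeoTIFF-style I/O, masking and resampling.

A :class:`GridStack` is the package's in-memory container for an annual raster
time series — a float array indexed ``(year, row, col)`` plus the grid
geometry (origin, pixel size, CRS code) and a nodata convention.  All
downstream statistics treat NaN as nodata and never let it leak into valid
cells.

Files are written as multipage float32/float64 TIFF (one page per year) with
the grid metadata serialized as JSON into the ImageDescription tag, so a
stack round-trips bit-exactly through a single plain TIFF file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage


class AlignmentError(ValueError):
    """Raised when two grids do not share shape, transform or CRS."""


@dataclass(frozen=True)
class GridTransform:
    """Affine grid geometry: map coordinates of the (0, 0) cell *corner*.

    ``x = x_origin + col * pixel_width``; ``y = y_origin - row * pixel_height``
    (row 0 at north).  Cell values represent the full cell.
    """

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_width: float = 1.0
    pixel_height: float = 1.0

    def close_to(self, other: "GridTransform", rtol: float = 1e-9) -> bool:
        a = (self.x_origin, self.y_origin, self.pixel_width, self.pixel_height)
        b = (other.x_origin, other.y_origin, other.pixel_width, other.pixel_height)
        return bool(np.allclose(a, b, rtol=rtol, atol=1e-12))


@dataclass
class GridStack:
    """An annual raster time series on a fixed grid.

    Parameters
    ----------
    values : ndarray, shape (n_years, n_rows, n_cols)
        Float data; NaN marks nodata.
    years : sequence of int
        Strictly increasing, one per band.
    variable : str
        Variable name (e.g. ``"ndvi"``, ``"temperature"``).
    units : str
        Physical units; dimensionless quantities use ``""``.
    transform : GridTransform
    crs_id : str
        Free-form CRS code (e.g. ``"EPSG:32647"``); inputs must share it.
    """

    values: np.ndarray
    years: np.ndarray
    variable: str = "ndvi"
    units: str = ""
    transform: GridTransform = field(default_factory=GridTransform)
    crs_id: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D (year, row, col), got {self.values.ndim}-D")
        if self.years.ndim != 1 or len(self.years) != self.values.shape[0]:
            raise ValueError(
                f"years length {len(self.years)} != number of bands {self.values.shape[0]}"
            )
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (n_rows, n_cols)."""
        return self.values.shape[1:]

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean (row, col): True where *any* year is nodata."""
        return np.isnan(self.values).any(axis=0)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean (row, col): True where every year is valid."""
        return ~self.nodata_mask

    def same_grid(self, other: "GridStack") -> bool:
        return (
            self.shape == other.shape
            and self.transform.close_to(other.transform)
            and self.crs_id == other.crs_id
        )

    def require_same_grid(self, other: "GridStack") -> None:
        if not self.same_grid(other):
            raise AlignmentError(
                f"grids not aligned: shape {self.shape} vs {other.shape}, "
                f"transform {self.transform} vs {other.transform}, "
                f"crs {self.crs_id!r} vs {other.crs_id!r}"
            )

    def copy(self, values: np.ndarray | None = None, **kw) -> "GridStack":
        out = replace(self, **kw)
        out.values = np.array(self.values if values is None else values, dtype=float)
        out.years = self.years.copy()
        return out


@dataclass
class Mask:
    """Boolean include/exclude layer on the same grid as a stack.

    ``values`` is True for cells to *include*; ``provenance`` records what the
    mask represents (``grassland``, ``road_river``, ``custom``).
    """

    values: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D (row, col)")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _meta_dict(stack: GridStack) -> dict:
    t = stack.transform
    return {
        "grasstrend": 1,
        "years": [int(y) for y in stack.years],
        "variable": stack.variable,
        "units": stack.units,
        "transform": [t.x_origin, t.y_origin, t.pixel_width, t.pixel_height],
        "crs_id": stack.crs_id,
    }


def write_stack(stack: GridStack, path: str | Path) -> Path:
    """Write a stack as a multipage float TIFF with JSON metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.values.astype(np.float64),
        photometric="minisblack",
        description=json.dumps(_meta_dict(stack)),
    )
    return path


def read_stack(
    paths: str | Path | Sequence[str | Path],
    years: Iterable[int] | None = None,
    variable: str | None = None,
) -> GridStack:
    """Read a stack from one multipage file or a list of single-band files.

    Band order follows the file/page order; ``years`` overrides any years
    stored in the file metadata and is required for plain files without it.
    Bands must be co-registered: same shape and (when metadata is present)
    same transform and CRS.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    bands: list[np.ndarray] = []
    metas: list[dict] = []
    for p in paths:
        with tifffile.TiffFile(Path(p)) as tf:
            arr = tf.asarray().astype(float)
            desc = tf.pages[0].description
            meta = {}
            if desc:
                try:
                    meta = json.loads(desc)
                except (ValueError, TypeError):
                    meta = {}
            if arr.ndim == 2:
                arr = arr[None]
            bands.append(arr)
            metas.append(meta if meta.get("grasstrend") else {})

    shapes = {b.shape[1:] for b in bands}
    if len(shapes) != 1:
        raise AlignmentError(f"input bands have differing shapes: {sorted(shapes)}")
    transforms = [
        GridTransform(*m["transform"]) for m in metas if "transform" in m
    ]
    for t in transforms[1:]:
        if not transforms[0].close_to(t):
            raise AlignmentError("input files have differing transforms (pixel size/origin)")
    crs_ids = {m["crs_id"] for m in metas if "crs_id" in m}
    if len(crs_ids) > 1:
        raise AlignmentError(f"input files have differing CRS codes: {sorted(crs_ids)}")

    values = np.concatenate(bands, axis=0)
    meta0 = next((m for m in metas if m), {})
    if years is None:
        if "years" in meta0 and len(meta0["years"]) == values.shape[0]:
            years = meta0["years"]
        else:
            raise ValueError("years not given and not recoverable from file metadata")
    years = np.asarray(list(years), dtype=int)
    if len(years) != values.shape[0]:
        raise ValueError(f"{len(years)} years given for {values.shape[0]} bands")
    return GridStack(
        values=values,
        years=years,
        variable=variable or meta0.get("variable", "ndvi"),
        units=meta0.get("units", ""),
        transform=transforms[0] if transforms else GridTransform(),
        crs_id=meta0.get("crs_id", "local"),
    )


def write_mask(mask: Mask, path: str | Path, transform: GridTransform | None = None,
               crs_id: str = "local") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = transform or GridTransform()
    meta = {
        "grasstrend": 1,
        "mask": True,
        "provenance": mask.provenance,
        "transform": [t.x_origin, t.y_origin, t.pixel_width, t.pixel_height],
        "crs_id": crs_id,
    }
    tifffile.imwrite(path, mask.values.astype(np.uint8), description=json.dumps(meta))
    return path


def read_mask(path: str | Path) -> Mask:
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    prov = "custom"
    if desc:
        try:
            prov = json.loads(desc).get("provenance", "custom")
        except (ValueError, TypeError):
            pass
    return Mask(values=arr.astype(bool), provenance=prov)


# ---------------------------------------------------------------------------
# Resampling and masking
# ---------------------------------------------------------------------------

def _extent(stack: GridStack) -> tuple[float, float, float, float]:
    t = stack.transform
    nr, nc = stack.shape
    x0, x1 = t.x_origin, t.x_origin + nc * t.pixel_width
    y1, y0 = t.y_origin, t.y_origin - nr * t.pixel_height
    return x0, x1, y0, y1  # xmin, xmax, ymin, ymax


def resample_to(stack: GridStack, target: GridStack, method: str = "bilinear") -> GridStack:
    """Resample ``stack`` onto ``target``'s grid by nearest or bilinear.

    Interpolation works in cell-center map coordinates.  Nodata is never
    interpolated into valid cells: with bilinear, any target cell whose
    footprint touches a nodata source cell becomes nodata.  Outside the
    source extent cells are nodata (edge values are extended up to half a
    source cell, matching cell-center semantics).
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if stack.crs_id != target.crs_id:
        raise AlignmentError(f"CRS mismatch: {stack.crs_id!r} vs {target.crs_id!r}")
    sx0, sx1, sy0, sy1 = _extent(stack)
    tx0, tx1, ty0, ty1 = _extent(target)
    if tx1 <= sx0 or tx0 >= sx1 or ty1 <= sy0 or ty0 >= sy1:
        raise AlignmentError("source and target extents are disjoint")

    if stack.same_grid(target):
        return stack.copy()

    ts, ss = target.transform, stack.transform
    nr, nc = target.shape
    # target cell-center map coordinates
    xc = ts.x_origin + (np.arange(nc) + 0.5) * ts.pixel_width
    yc = ts.y_origin - (np.arange(nr) + 0.5) * ts.pixel_height
    # fractional source indices of those centers
    col_f = (xc - ss.x_origin) / ss.pixel_width - 0.5
    row_f = (ss.y_origin - yc) / ss.pixel_height - 0.5
    cols, rows = np.meshgrid(col_f, row_f)
    snr, snc = stack.shape
    inside = (rows > -0.5) & (rows < snr - 0.5) & (cols > -0.5) & (cols < snc - 0.5)

    order = 0 if method == "nearest" else 1
    out = np.full((stack.n_years, nr, nc), np.nan)
    src_bad = np.isnan(stack.values)
    for b in range(stack.n_years):
        band = np.where(src_bad[b], 0.0, stack.values[b])
        interp = ndimage.map_coordinates(
            band, [rows, cols], order=order, mode="nearest"
        )
        touched = ndimage.map_coordinates(
            src_bad[b].astype(float), [rows, cols], order=order, mode="nearest"
        )
        interp[(touched > 0) | ~inside] = np.nan
        out[b] = interp
    res = stack.copy(values=out)
    res.transform = target.transform
    return res


def apply_mask(stack: GridStack, mask: Mask, buffer_pixels: int = 0) -> GridStack:
    """Set excluded cells (mask False), dilated by ``buffer_pixels``, to nodata.

    Dilation uses a square (queen) structuring element so a buffer of one
    pixel turns a single excluded cell into a 3x3 nodata block.  Idempotent.
    """
    if mask.values.shape != stack.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match stack spatial shape {stack.shape}"
        )
    if buffer_pixels < 0:
        raise ValueError("buffer_pixels must be >= 0")
    excluded = ~mask.values
    if buffer_pixels > 0 and excluded.any():
        excluded = ndimage.binary_dilation(
            excluded, structure=np.ones((3, 3), bool), iterations=buffer_pixels
        )
    out = stack.copy()
    out.values[:, excluded] = np.nan
    return out
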
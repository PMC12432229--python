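"""Lightweight georeferenced raster container and grid utilities.

All layers live in a single projected coordinate system with metre units.
The container stores a ``(bands, rows, cols)`` float32 array together with
a GDAL-style geotransform; rows increase southward (y decreases), columns
increase eastward.  I/O is plain TIFF via :mod:`tifffile` with the geo
metadata (transform, CRS id, nodata, band labels) serialized as JSON in the
image description tag, so rasters round-trip without a GDAL dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

DEFAULT_NODATA = -9999.0


@dataclass
class GridSpec:
    """Pixel grid geometry: top-left origin and square-ish pixel size."""

    x0: float
    y0: float
    px: float  # pixel width (m), > 0
    py: float  # pixel height (m), > 0; y decreases with row index
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.px <= 0 or self.py <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive shape")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        return (
            self.x0,
            self.y0 - self.rows * self.py,
            self.x0 + self.cols * self.px,
            self.y0,
        )

    @property
    def pixel_area(self) -> float:
        return self.px * self.py

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(cols) + 0.5) * self.px
        y = self.y0 - (np.asarray(rows) + 0.5) * self.py
        return x, y

    def index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel containing each point (no bounds check)."""
        col = np.floor((np.asarray(x) - self.x0) / self.px).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.py).astype(int)
        return row, col

    def geotransform(self) -> tuple[float, float, float, float, float, float]:
        return (self.x0, self.px, 0.0, self.y0, 0.0, -self.py)


@dataclass
class MultibandRaster:
    """A stack of co-registered bands on one :class:`GridSpec`.

    Band order convention for imagery is B, G, R, NIR and optionally DEM
    as a fifth band.  ``nodata`` marks invalid pixels consistently across
    bands (a pixel is invalid iff band 0 equals nodata).
    """

    data: np.ndarray  # (bands, rows, cols), float32
    grid: GridSpec
    crs: str = "LOCAL_METRIC"
    nodata: float = DEFAULT_NODATA
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("data must be (bands, rows, cols)")
        b, r, c = self.data.shape
        if (r, c) != (self.grid.rows, self.grid.cols):
            raise ValueError(f"data shape {(r, c)} does not match grid {(self.grid.rows, self.grid.cols)}")
        if not self.band_names:
            self.band_names = [f"band_{i + 1}" for i in range(b)]

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def valid_mask(self) -> np.ndarray:
        return self.data[0] != self.nodata

    def same_grid(self, other: "MultibandRaster") -> bool:
        g, h = self.grid, other.grid
        return (
            (g.rows, g.cols) == (h.rows, h.cols)
            and np.allclose([g.x0, g.y0, g.px, g.py], [h.x0, h.y0, h.px, h.py])
        )

    def copy(self) -> "MultibandRaster":
        return replace(self, data=self.data.copy(), band_names=list(self.band_names))

    # ---------------------------------------------------------------- I/O
    def write(self, path: str) -> None:
        meta = {
            "geotransform": self.grid.geotransform(),
            "crs": self.crs,
            "nodata": self.nodata,
            "band_names": self.band_names,
        }
        arr = self.data[0] if self.n_bands == 1 else np.moveaxis(self.data, 0, -1)
        kwargs = {} if self.n_bands == 1 else {"planarconfig": "contig"}
        tifffile.imwrite(
            path,
            arr,
            description=json.dumps(meta),
            photometric="minisblack",
            **kwargs,
        )

    @classmethod
    def read(cls, path: str) -> "MultibandRaster":
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if arr.ndim == 2:
            arr = arr[..., None]
        data = np.moveaxis(arr, -1, 0)
        x0, px, _, y0, _, npy = meta["geotransform"]
        grid = GridSpec(x0=x0, y0=y0, px=px, py=-npy, rows=data.shape[1], cols=data.shape[2])
        return cls(
            data=data,
            grid=grid,
            crs=meta.get("crs", "LOCAL_METRIC"),
            nodata=meta.get("nodata", DEFAULT_NODATA),
            band_names=meta.get("band_names", []),
        )


def make_grid(bounds: tuple[float, float, float, float], pixel_size: float) -> GridSpec:
    """Grid covering ``bounds`` (xmin, ymin, xmax, ymax) at ``pixel_size`` m."""
    xmin, ymin, xmax, ymax = bounds
    cols = int(round((xmax - xmin) / pixel_size))
    rows = int(round((ymax - ymin) / pixel_size))
    return GridSpec(x0=xmin, y0=ymax, px=pixel_size, py=pixel_size, rows=rows, cols=cols)


def rasterize(
    geoms,
    grid: GridSpec,
    values=None,
    out: np.ndarray | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Burn geometries into a grid using the pixel-centre rule.

    A pixel belongs to a geometry iff its centre lies inside it, so interior
    rings (holes) are honoured exactly.  Later geometries overwrite earlier
    ones where they overlap.
    """
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    if out is None:
        out = np.zeros((grid.rows, grid.cols), dtype=dtype)
    if values is None:
        values = np.ones(len(geoms))
    for geom, val in zip(geoms, np.broadcast_to(values, (len(geoms),))):
        if geom.is_empty:
            continue
        xmin, ymin, xmax, ymax = geom.bounds
        r1, c0 = grid.index(np.array(xmin), np.array(ymax))
        r2, c1 = grid.index(np.array(xmax), np.array(ymin))
        r1, r2 = max(int(r1), 0), min(int(r2) + 1, grid.rows)
        c0, c1 = max(int(c0), 0), min(int(c1) + 1, grid.cols)
        if r1 >= r2 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r1, r2), np.arange(c0, c1), indexing="ij")
        xs, ys = grid.cell_centers(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(geom, xs, ys).reshape(rr.shape)
        out[r1:r2, c0:c1][inside] = val
    return out


def resample_to_grid(src: MultibandRaster, target: GridSpec, order: int = 3) -> MultibandRaster:
    """Resample ``src`` onto ``target`` by spline interpolation in map space.

    ``order=3`` is bicubic (continuous imagery); ``order=0`` is nearest
    neighbour and must be used for label/mask rasters.
    """
    rr, cc = np.meshgrid(np.arange(target.rows), np.arange(target.cols), indexing="ij")
    xs, ys = target.cell_centers(rr, cc)
    # fractional pixel coordinates in the source grid (centre convention)
    src_c = (xs - src.grid.x0) / src.grid.px - 0.5
    src_r = (src.grid.y0 - ys) / src.grid.py - 0.5
    coords = np.stack([src_r, src_c])
    out = np.empty((src.n_bands, target.rows, target.cols), dtype=np.float32)
    for b in range(src.n_bands):
        out[b] = ndimage.map_coordinates(
            src.data[b].astype(np.float64), coords, order=order, mode="nearest"
        )
    return MultibandRaster(
        data=out, grid=target, crs=src.crs, nodata=src.nodata, band_names=list(src.band_names)
    )


def block_mean(raster: MultibandRaster, factor: int) -> MultibandRaster:
    """Aggregate by an integer factor with a block mean (area-weighted)."""
    b, r, c = raster.data.shape
    if r % factor or c % factor:
        raise ValueError("extent not divisible by aggregation factor")
    data = raster.data.reshape(b, r // factor, factor, c // factor, factor).mean(axis=(2, 4))
    g = raster.grid
    grid = GridSpec(x0=g.x0, y0=g.y0, px=g.px * factor, py=g.py * factor, rows=r // factor, cols=c // factor)
    return MultibandRaster(data=data, grid=grid, crs=raster.crs, nodata=raster.nodata, band_names=list(raster.band_names))
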
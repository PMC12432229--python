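"""Radiometrically harmonized annual composites from overlapping scenes.

The mosaicking stage mirrors common practice for multi-scene nano-satellite
imagery: every scene of a year is histogram-matched (monotone quantile
mapping, per band) to a coarse jitter-free reference composite, merged onto
the tile grid with a per-pixel medoid rule in overlaps, and finally stacked
with a bicubically resampled elevation band.

The medoid of a set of spectral vectors is the *observation* minimizing the
summed distance to all other observations — it never invents spectra, which
is why it is preferred over means for compositing.
"""

from __future__ import annotations

import numpy as np

from .raster import GridSpec, MultibandRaster, resample_to_grid


def _medoid_index(obs: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Index of the medoid along axis 0 of ``obs`` (n_obs, bands, npix)."""
    if metric == "euclidean":
        diff = obs[:, None] - obs[None, :]              # (n, n, bands, npix)
        dist = np.sqrt((diff ** 2).sum(axis=2))         # (n, n, npix)
    elif metric == "manhattan":
        dist = np.abs(obs[:, None] - obs[None, :]).sum(axis=2)
    else:
        raise ValueError(f"unknown metric: {metric}")
    return dist.sum(axis=1).argmin(axis=0)              # (npix,)


def medoid_composite(stack: list[MultibandRaster], metric: str = "euclidean") -> MultibandRaster:
    """Pixel-wise medoid across co-registered rasters.

    Pixels invalid in some scenes use the medoid of the valid observations
    only; pixels valid nowhere are nodata.
    """
    if not stack:
        raise ValueError("empty stack")
    first = stack[0]
    for r in stack[1:]:
        if not first.same_grid(r):
            raise ValueError("rasters are not co-registered on the same grid")
    if len(stack) == 1:
        return first.copy()

    n = len(stack)
    bands, rows, cols = stack[0].data.shape
    data = np.stack([r.data for r in stack])            # (n, bands, rows, cols)
    valid = np.stack([r.valid_mask() for r in stack])   # (n, rows, cols)
    out = np.full((bands, rows, cols), first.nodata, dtype=np.float32)

    nv = valid.sum(axis=0)
    flat = data.reshape(n, bands, -1)
    vflat = valid.reshape(n, -1)
    outf = out.reshape(bands, -1)
    # group pixels by their validity pattern so the medoid is vectorized
    for pattern in np.unique(vflat, axis=1).T:
        k = int(pattern.sum())
        if k == 0:
            continue
        cols_sel = np.flatnonzero((vflat == pattern[:, None]).all(axis=0))
        obs = flat[np.flatnonzero(pattern)][:, :, cols_sel]   # (k, bands, m)
        if k == 1:
            outf[:, cols_sel] = obs[0]
        else:
            idx = _medoid_index(obs, metric)
            outf[:, cols_sel] = np.take_along_axis(obs, idx[None, None, :], axis=0)[0]
    out = outf.reshape(bands, rows, cols)
    out[:, nv == 0] = first.nodata
    return MultibandRaster(data=out, grid=first.grid, crs=first.crs,
                           nodata=first.nodata, band_names=list(first.band_names))


def histogram_match(source: MultibandRaster, reference: MultibandRaster) -> MultibandRaster:
    """Monotone quantile mapping of each source band to the reference band.

    The reference may be on a different (typically coarser) grid; only the
    empirical distributions matter.  Valid-pixel masks are preserved.
    """
    if source.n_bands != reference.n_bands:
        raise ValueError("band count mismatch between source and reference")
    src_valid = source.valid_mask()
    ref_valid = reference.valid_mask()
    if not src_valid.any() or not ref_valid.any():
        raise ValueError("no valid pixels to match")
    out = source.data.copy()
    for b in range(source.n_bands):
        s = source.data[b][src_valid].astype(np.float64)
        r = reference.data[b][ref_valid].astype(np.float64)
        # mid-rank quantile of each source value within its own
        # distribution (ties share their average rank), mapped through the
        # reference's empirical inverse CDF at the same mid-rank positions
        # so that matching a distribution to itself is a fixed point
        sorted_s = np.sort(s)
        lo = np.searchsorted(sorted_s, s, side="left")
        hi = np.searchsorted(sorted_s, s, side="right")
        q = (lo + hi) / 2.0 / len(s)
        ref_q = (np.arange(len(r)) + 0.5) / len(r)
        matched = np.interp(q, ref_q, np.sort(r))
        band = out[b]
        band[src_valid] = matched.astype(np.float32)
    return MultibandRaster(data=out, grid=source.grid, crs=source.crs,
                           nodata=source.nodata, band_names=list(source.band_names))


def _paste(target: np.ndarray, target_grid: GridSpec, scene: MultibandRaster) -> tuple[slice, slice, np.ndarray]:
    """Window of ``target`` covered by ``scene`` plus the scene data clipped to it."""
    g = scene.grid
    c0 = int(round((g.x0 - target_grid.x0) / target_grid.px))
    r0 = int(round((target_grid.y0 - g.y0) / target_grid.py))
    r1, c1 = r0 + g.rows, c0 + g.cols
    sr0, sc0 = max(-r0, 0), max(-c0, 0)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, target_grid.rows), min(c1, target_grid.cols)
    return (slice(r0, r1), slice(c0, c1),
            scene.data[:, sr0: sr0 + (r1 - r0), sc0: sc0 + (c1 - c0)])


def build_annual_composite(
    scenes: list[MultibandRaster],
    reference: MultibandRaster,
    tile_grid: GridSpec | None = None,
    metric: str = "euclidean",
) -> MultibandRaster:
    """Histogram-match every scene to the reference, then merge.

    Overlapping pixels take the per-pixel medoid across contributing scenes
    (a single contributor passes through unchanged), which keeps seams at
    the noise floor once the radiometry is matched.
    """
    if not scenes:
        raise ValueError("no scenes to composite")
    matched = [histogram_match(s, reference) for s in scenes]
    if tile_grid is None:
        xmin = min(s.grid.bounds[0] for s in scenes)
        ymin = min(s.grid.bounds[1] for s in scenes)
        xmax = max(s.grid.bounds[2] for s in scenes)
        ymax = max(s.grid.bounds[3] for s in scenes)
        g = scenes[0].grid
        from .raster import make_grid

        tile_grid = make_grid((xmin, ymin, xmax, ymax), g.px)
    nodata = scenes[0].nodata
    bands = scenes[0].n_bands
    # expand every matched scene onto the tile grid, then medoid-merge
    expanded = []
    for s in matched:
        canvas = np.full((bands, tile_grid.rows, tile_grid.cols), nodata, dtype=np.float32)
        rs, cs, chunk = _paste(canvas, tile_grid, s)
        canvas[:, rs, cs] = chunk
        expanded.append(MultibandRaster(data=canvas, grid=tile_grid, crs=s.crs,
                                        nodata=nodata, band_names=list(s.band_names)))
    return medoid_composite(expanded, metric=metric)


def stack_elevation(composite: MultibandRaster, dem: MultibandRaster) -> MultibandRaster:
    """Append elevation as a fifth band, bicubically resampled to the grid."""
    if composite.same_grid(dem):
        band5 = dem.data[0:1]
    else:
        band5 = resample_to_grid(dem, composite.grid, order=3).data[0:1]
    data = np.concatenate([composite.data, band5.astype(np.float32)], axis=0)
    return MultibandRaster(data=data, grid=composite.grid, crs=composite.crs,
                           nodata=composite.nodata,
                           band_names=list(composite.band_names) + ["dem"])
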
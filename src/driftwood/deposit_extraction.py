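"""Fusing annual detections into stable deposits, filtering, vectorizing.

Annual binary predictions are combined per pixel into a presence
probability (fraction of observed years with a detection).  Two thresholds
then act together: pixels at probability >= 0.6 *seed* a deposit (with
three years this means detection in at least two), while the deposit's
shape is grown over the connected region at probability >= 0.5.  This keeps
stable deposits, fills single-year gaps at their margins, and rejects
transient single-year detections.

Extracted regions are vectorized to polygons (interior rings preserved,
planar pixel areas) and filtered by the mapping rules: drop deposits whose
footprint is more than 20% water, deposits touching roads or buildings,
and deposits with more than 5 holes (a common raster-artifact signature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union
from shapely.strtree import STRtree
from skimage import measure

from .raster import GridSpec


@dataclass
class Deposit:
    """A vectorized driftwood deposit with its accounting attributes."""

    id: int
    geometry: object                 # shapely (Multi)Polygon
    area_m2: float
    hole_count: int
    pixel_count: int
    water_fraction: float = 0.0
    year_support: float = 1.0        # years detected / years observed
    distance_to_mouth_km: float = math.nan
    catchment_id: int = -1
    setting: str = "unassigned"      # deltaic | coastal | unassigned
    cluster_member: bool = False
    pixels: np.ndarray | None = field(default=None, repr=False)  # (k, 2) row/col


def presence_probability(annual_masks: list[np.ndarray],
                         observed_masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-pixel fraction of observed years with a detection.

    ``observed_masks`` marks which pixels had valid imagery in each year;
    years without an observation are excluded from the denominator.  Pixels
    never observed are NaN.
    """
    if len(annual_masks) < 2:
        raise ValueError("need at least two annual masks to fuse")
    det = np.stack([m.astype(bool) for m in annual_masks])
    if observed_masks is None:
        obs = np.ones_like(det, dtype=bool)
    else:
        if len(observed_masks) != len(annual_masks):
            raise ValueError("observed_masks must match annual_masks")
        obs = np.stack([m.astype(bool) for m in observed_masks])
    n_obs = obs.sum(axis=0)
    n_det = (det & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(n_obs > 0, n_det / np.maximum(n_obs, 1), np.nan)
    return prob


def extract_deposits(
    prob: np.ndarray,
    grid: GridSpec,
    t_presence: float = 0.6,
    t_shape: float = 0.5,
    connectivity: int = 2,
) -> list[Deposit]:
    """Seeded dual-threshold extraction.

    Connected components (8-connected by default) of the shape mask
    (prob >= ``t_shape``) become deposits iff they contain at least one
    presence seed (prob >= ``t_presence``).
    """
    if not (0 < t_shape <= 1 and 0 < t_presence <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if t_shape > t_presence:
        raise ValueError("t_shape must not exceed t_presence")
    finite = np.isfinite(prob)
    shape_mask = finite & (prob >= t_shape)
    seed_mask = finite & (prob >= t_presence)
    lab = measure.label(shape_mask, connectivity=connectivity)
    if lab.max() == 0:
        return []
    seeded = np.unique(lab[seed_mask])
    seeded = seeded[seeded > 0]
    deposits = []
    for i, comp in enumerate(seeded):
        pix = np.argwhere(lab == comp)
        geom = pixels_to_polygon(pix, grid)
        holes = _hole_count(geom)
        deposits.append(
            Deposit(
                id=i,
                geometry=geom,
                area_m2=len(pix) * grid.pixel_area,
                hole_count=holes,
                pixel_count=len(pix),
                pixels=pix,
            )
        )
    return deposits


def pixels_to_polygon(pixels: np.ndarray, grid: GridSpec):
    """Union of pixel footprint squares; interior rings appear naturally."""
    boxes = []
    for r, c in pixels:
        x0 = grid.x0 + c * grid.px
        y1 = grid.y0 - r * grid.py
        boxes.append(box(x0, y1 - grid.py, x0 + grid.px, y1))
    return unary_union(boxes)


def _hole_count(geom) -> int:
    if geom.geom_type == "Polygon":
        return len(geom.interiors)
    return sum(len(g.interiors) for g in geom.geoms)


def build_water_mask(landcover_water_flags: list[np.ndarray], persistence: float = 0.2) -> np.ndarray:
    """Pixel is water iff flagged water in strictly more than ``persistence``
    of the observations."""
    if not landcover_water_flags:
        raise ValueError("no water observations")
    flags = np.stack([f.astype(bool) for f in landcover_water_flags])
    return flags.mean(axis=0) > persistence


def compute_water_fractions(deposits: list[Deposit], water_mask: np.ndarray) -> None:
    """Fill ``water_fraction`` from each deposit's pixel footprint."""
    for d in deposits:
        if d.pixels is None or len(d.pixels) == 0:
            d.water_fraction = 0.0
        else:
            d.water_fraction = float(water_mask[d.pixels[:, 0], d.pixels[:, 1]].mean())


def filter_deposits(
    deposits: list[Deposit],
    water_mask: np.ndarray | None = None,
    infrastructure: list | None = None,
    max_water_fraction: float = 0.2,
    max_holes: int = 5,
) -> tuple[list[Deposit], list[dict]]:
    """Apply the removal rules; the log records the first failed rule.

    Rules, in order: water coverage strictly greater than
    ``max_water_fraction``; intersection with any road/building feature;
    strictly more than ``max_holes`` interior rings.
    """
    if water_mask is not None:
        compute_water_fractions(deposits, water_mask)
    tree = STRtree([g for g in infrastructure]) if infrastructure else None
    kept, log = [], []
    for d in deposits:
        if d.water_fraction > max_water_fraction:
            log.append({"id": d.id, "rule": "water", "value": d.water_fraction})
            continue
        if tree is not None:
            hits = tree.query(d.geometry, predicate="intersects")
            if len(hits):
                log.append({"id": d.id, "rule": "infrastructure", "value": int(len(hits))})
                continue
        if d.hole_count > max_holes:
            log.append({"id": d.id, "rule": "holes", "value": d.hole_count})
            continue
        kept.append(d)
    return kept, log


def vectorize_and_measure(binary: np.ndarray, grid: GridSpec, connectivity: int = 2) -> list[Deposit]:
    """Vectorize all positive regions of a binary raster with exact planar
    pixel areas and interior-ring counts."""
    lab = measure.label(binary.astype(bool), connectivity=connectivity)
    out = []
    for comp in range(1, lab.max() + 1):
        pix = np.argwhere(lab == comp)
        geom = pixels_to_polygon(pix, grid)
        out.append(
            Deposit(
                id=comp - 1,
                geometry=geom,
                area_m2=len(pix) * grid.pixel_area,
                hole_count=_hole_count(geom),
                pixel_count=len(pix),
                pixels=pix,
            )
        )
    return out


def year_support(deposits: list[Deposit], annual_masks: list[np.ndarray],
                 observed_masks: list[np.ndarray] | None = None) -> None:
    """Fill ``year_support`` = mean over footprint pixels of detected/observed."""
    prob = presence_probability(annual_masks, observed_masks)
    for d in deposits:
        if d.pixels is not None and len(d.pixels):
            vals = prob[d.pixels[:, 0], d.pixels[:, 1]]
            d.year_support = float(np.nanmean(vals))
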
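"""Coarse-vs-fine evaluation of mapped driftwood.

The coarse-resolution prediction is compared against a high-resolution
reference segmentation by aggregating both deposit sets onto a square grid
(default 512 m cells) and regressing predicted area on reference area per
cell (r^2, slope), together with the overall relative bias

    bias% = 100 * (sum(pred) - sum(ref)) / sum(ref)

and a size-stratified bias: reference deposits are binned by area (default
edges 100 and 10,000 m^2), predictions are matched to reference deposits by
greatest area overlap, and per-bin biases expose where omitted area
concentrates (typically below the coarse sensor's minimum mapping unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.strtree import STRtree


@dataclass
class EvalReport:
    cell_size_m: float
    n_cells: int
    pred_area_per_cell: np.ndarray
    ref_area_per_cell: np.ndarray
    r_squared: float
    slope: float
    intercept: float
    slope_through_origin: float
    relative_bias_percent: float
    relative_bias_excluding_small_percent: float
    per_bin_bias_percent: dict
    per_bin_ref_share: dict
    commission_area_m2: float
    small_edge_m2: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["pred_area_per_cell"] = self.pred_area_per_cell.tolist()
        d["ref_area_per_cell"] = self.ref_area_per_cell.tolist()
        return d


def _cell_areas(geoms, extent, cell: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = extent
    nx = max(int(math.ceil((xmax - xmin) / cell)), 1)
    ny = max(int(math.ceil((ymax - ymin) / cell)), 1)
    out = np.zeros(nx * ny)
    cells = [box(xmin + i * cell, ymin + j * cell, xmin + (i + 1) * cell, ymin + (j + 1) * cell)
             for j in range(ny) for i in range(nx)]
    tree = STRtree(cells)
    for geom in geoms:
        for k in tree.query(geom, predicate="intersects"):
            out[k] += cells[k].intersection(geom).area
    return out


def grid_compare(
    pred_geoms: list,
    ref_geoms: list,
    cell_size_m: float = 512.0,
    extent: tuple[float, float, float, float] | None = None,
    bin_edges: tuple[float, ...] = (100.0, 10_000.0),
) -> EvalReport:
    """Square-grid comparison of predicted vs reference deposit area.

    Grid origin is aligned to the extent's lower-left corner (by default
    the union of both deposit sets' bounds).
    """
    flags = []
    if extent is None:
        all_geoms = list(pred_geoms) + list(ref_geoms)
        if not all_geoms:
            raise ValueError("no geometries to compare")
        bounds = np.array([g.bounds for g in all_geoms])
        extent = (bounds[:, 0].min(), bounds[:, 1].min(), bounds[:, 2].max(), bounds[:, 3].max())
    pred_cells = _cell_areas(pred_geoms, extent, cell_size_m)
    ref_cells = _cell_areas(ref_geoms, extent, cell_size_m)

    ref_total = ref_cells.sum()
    pred_total = pred_cells.sum()
    if ref_total == 0:
        flags.append("zero_reference_area")
        bias = math.nan
    else:
        bias = 100.0 * (pred_total - ref_total) / ref_total

    # OLS of pred on ref, free intercept, plus through-origin slope
    if ref_cells.std() > 0:
        slope, intercept = np.polyfit(ref_cells, pred_cells, 1)
        ss_res = np.sum((pred_cells - (slope * ref_cells + intercept)) ** 2)
        ss_tot = np.sum((pred_cells - pred_cells.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2 = max(min(r2, 1.0), 0.0)
        denom = float(ref_cells @ ref_cells)
        slope0 = float(pred_cells @ ref_cells) / denom if denom else math.nan
    else:
        flags.append("constant_reference_field")
        slope = intercept = slope0 = r2 = math.nan

    strat = size_stratified_bias(pred_geoms, ref_geoms, bin_edges)
    return EvalReport(
        cell_size_m=cell_size_m,
        n_cells=len(ref_cells),
        pred_area_per_cell=pred_cells,
        ref_area_per_cell=ref_cells,
        r_squared=float(r2),
        slope=float(slope),
        intercept=float(intercept),
        slope_through_origin=float(slope0),
        relative_bias_percent=float(bias),
        relative_bias_excluding_small_percent=strat["bias_excluding_small_percent"],
        per_bin_bias_percent=strat["per_bin_bias_percent"],
        per_bin_ref_share=strat["per_bin_ref_share"],
        commission_area_m2=strat["commission_area_m2"],
        small_edge_m2=bin_edges[0] if bin_edges else math.nan,
        flags=flags + strat["flags"],
    )


def _bin_label(area: float, edges: tuple[float, ...]) -> str:
    lo = 0.0
    for e in edges:
        if area < e:
            return f"[{lo:g},{e:g})"
        lo = e
    return f"[{lo:g},inf)"


def size_stratified_bias(
    pred_geoms: list,
    ref_geoms: list,
    bin_edges: tuple[float, ...] = (100.0, 10_000.0),
) -> dict:
    """Per-size-bin relative bias with greatest-overlap matching.

    Each prediction's area is credited to the reference deposit it overlaps
    most; predictions overlapping no reference deposit are pooled as
    commission area.  Reference deposits are binned by their own area.
    """
    flags = []
    edges = tuple(bin_edges)
    labels = []
    lo = 0.0
    for e in list(edges) + [math.inf]:
        labels.append(f"[{lo:g},{'inf' if math.isinf(e) else format(e, 'g')})")
        lo = e

    ref_areas = np.array([g.area for g in ref_geoms])
    ref_bin = [_bin_label(a, edges) for a in ref_areas]
    ref_area_by_bin = {lab: 0.0 for lab in labels}
    pred_area_by_bin = {lab: 0.0 for lab in labels}
    for a, lab in zip(ref_areas, ref_bin):
        ref_area_by_bin[lab] += a

    commission = 0.0
    if ref_geoms:
        tree = STRtree(list(ref_geoms))
        for pg in pred_geoms:
            hits = tree.query(pg, predicate="intersects")
            if len(hits) == 0:
                commission += pg.area
                continue
            overlaps = [ref_geoms[int(k)].intersection(pg).area for k in hits]
            best = int(hits[int(np.argmax(overlaps))])
            pred_area_by_bin[ref_bin[best]] += pg.area
    else:
        commission = sum(g.area for g in pred_geoms)

    per_bin_bias = {}
    per_bin_share = {}
    ref_total = ref_areas.sum()
    for lab in labels:
        ra, pa = ref_area_by_bin[lab], pred_area_by_bin[lab]
        per_bin_share[lab] = ra / ref_total if ref_total > 0 else math.nan
        if ra == 0:
            per_bin_bias[lab] = math.nan
            flags.append(f"empty_bin:{lab}")
        else:
            per_bin_bias[lab] = 100.0 * (pa - ra) / ra

    # bias with reference deposits below the smallest edge excluded
    if edges:
        big = [lab for lab in labels[1:]]
        ra = sum(ref_area_by_bin[lab] for lab in big)
        pa = sum(pred_area_by_bin[lab] for lab in big)
        excl = 100.0 * (pa - ra) / ra if ra > 0 else math.nan
    else:
        excl = math.nan
    return {
        "per_bin_bias_percent": per_bin_bias,
        "per_bin_ref_share": per_bin_share,
        "bias_excluding_small_percent": float(excl),
        "commission_area_m2": float(commission),
        "flags": flags,
    }
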
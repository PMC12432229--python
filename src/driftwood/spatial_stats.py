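"""Hex-grid aggregation, spatial autocorrelation, and coastal analyses.

The driftwood cover field is aggregated to a regular hexagonal grid
(default cell size 10 km, measured as the hexagon incircle diameter).
Spatial structure is quantified with Global Moran's I and per-cell Anselin
Local Moran's I (LISA) under conditional permutation inference; contiguity
is the six edge-sharing hexagon neighbours (queen and rook coincide on a
hexagonal tessellation), row-standardized.

Group comparisons use the Mann-Whitney U test (exact enumeration for small
samples, tie/continuity-corrected normal approximation otherwise) and rank
correlations use Spearman's rho (exact for n <= 8).  Bayesian counterparts
live in :mod:`driftwood.bayes`.  Catchment assignment follows the rule that
non-forested catchments hand their deposits to the nearest forested
catchment along the coastline; distance decay measures the area-weighted
cumulative driftwood cover against distance to the nearest river mouth.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from shapely.geometry import Point, Polygon, box
from shapely.strtree import STRtree


@dataclass
class StatResult:
    """Container for one statistic with frequentist and Bayesian summaries."""

    statistic: float
    p_value: float
    method: str
    bayes_factor_10: float = math.nan
    hdi_low: float = math.nan
    hdi_high: float = math.nan
    extras: dict = field(default_factory=dict)


@dataclass
class HexCell:
    id: int
    polygon: Polygon
    q: int
    r: int
    neighbors: list[int] = field(default_factory=list)
    driftwood_area_m2: float = 0.0
    land_area_m2: float = 0.0
    cover_fraction: float = 0.0
    deposit_count: int = 0
    density_per_km2: float = 0.0
    local_i: float = math.nan
    pseudo_p: float = math.nan
    quadrant: str = "not-significant"


# ------------------------------------------------------------------ hex grid
def make_hex_grid(extent: tuple[float, float, float, float], cell_size_m: float = 10_000.0) -> list[HexCell]:
    """Pointy-top hexagonal tessellation covering ``extent``.

    ``cell_size_m`` is the incircle diameter (flat-to-flat width).  Cells
    carry their six edge-sharing neighbour ids.
    """
    if cell_size_m <= 0:
        raise ValueError("cell size must be positive")
    xmin, ymin, xmax, ymax = extent
    s = cell_size_m
    R = s / math.sqrt(3.0)          # circumradius
    dy = 1.5 * R
    r0 = int(math.floor((ymin - R) / dy)) - 1
    r1 = int(math.ceil((ymax + R) / dy)) + 1
    cells: list[HexCell] = []
    index: dict[tuple[int, int], int] = {}
    ext_box = box(xmin, ymin, xmax, ymax)
    angles = np.deg2rad([90, 150, 210, 270, 330, 30])
    for r in range(r0, r1 + 1):
        cy = r * dy
        # axial x = s * (q + r/2)
        q0 = int(math.floor((xmin - s) / s - r / 2)) - 1
        q1 = int(math.ceil((xmax + s) / s - r / 2)) + 1
        for q in range(q0, q1 + 1):
            cx = s * (q + r / 2.0)
            verts = [(cx + R * math.cos(a), cy + R * math.sin(a)) for a in angles]
            poly = Polygon(verts)
            if not poly.intersects(ext_box):
                continue
            index[(q, r)] = len(cells)
            cells.append(HexCell(id=len(cells), polygon=poly, q=q, r=r))
    for cell in cells:
        for dq, dr in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)):
            j = index.get((cell.q + dq, cell.r + dr))
            if j is not None:
                cell.neighbors.append(j)
    return cells


def filter_cells(cells: list[HexCell], geometry) -> list[HexCell]:
    """Restrict a grid to cells intersecting ``geometry`` (e.g. the coastal
    band), reindexing ids and neighbour lists."""
    keep = [c for c in cells if c.polygon.intersects(geometry)]
    old_to_new = {c.id: i for i, c in enumerate(keep)}
    for i, c in enumerate(keep):
        c.id = i
        c.neighbors = [old_to_new[j] for j in c.neighbors if j in old_to_new]
    return keep


def aggregate_to_grid(
    geometries: list,
    cells: list[HexCell],
    land_geometry=None,
) -> list[HexCell]:
    """Distribute deposit area over cells by intersection; counts by centroid.

    ``land_geometry`` (optional) restricts each cell's land area used for
    cover fractions and densities; default is the full cell polygon.
    """
    tree = STRtree([c.polygon for c in cells])
    for c in cells:
        c.driftwood_area_m2 = 0.0
        c.deposit_count = 0
        land = c.polygon if land_geometry is None else c.polygon.intersection(land_geometry)
        c.land_area_m2 = land.area
    for geom in geometries:
        for j in tree.query(geom, predicate="intersects"):
            part = cells[j].polygon.intersection(geom)
            cells[j].driftwood_area_m2 += part.area
        cen = geom.centroid
        hits = tree.query(cen, predicate="within")
        if len(hits):
            cells[int(hits[0])].deposit_count += 1
    for c in cells:
        if c.land_area_m2 > 0:
            c.cover_fraction = min(c.driftwood_area_m2 / c.land_area_m2, 1.0)
            c.density_per_km2 = c.deposit_count / (c.land_area_m2 / 1e6)
        else:
            c.cover_fraction = 0.0
            c.density_per_km2 = 0.0
    return cells


def row_standardize(neighbors: list[list[int]]) -> list[np.ndarray]:
    return [np.full(len(nb), 1.0 / len(nb)) if nb else np.empty(0) for nb in neighbors]


# ------------------------------------------------------------------ Moran's I
def _moran_i_value(z: np.ndarray, neighbors: list[list[int]], weights: list[np.ndarray]) -> float:
    num = 0.0
    s0 = 0.0
    for i, (nb, wt) in enumerate(zip(neighbors, weights)):
        if len(nb):
            num += z[i] * float(wt @ z[np.asarray(nb)])
            s0 += wt.sum()
    n = len(z)
    return (n / s0) * num / float(z @ z)


def global_morans_i(
    values: np.ndarray,
    neighbors: list[list[int]],
    weights: list[np.ndarray] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> StatResult:
    """Global Moran's I with permutation pseudo-p.

    ``neighbors[i]`` lists the neighbour indices of unit i, ``weights[i]``
    the matching weights (row-standardized by default).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 units")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("constant field: Moran's I undefined")
    if weights is None:
        weights = row_standardize(neighbors)
    i_obs = _moran_i_value(z, neighbors, weights)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        zp = rng.permutation(z)
        perms[k] = _moran_i_value(zp, neighbors, weights)
    if alternative == "greater":
        exceed = int(np.sum(perms >= i_obs))
    elif alternative == "less":
        exceed = int(np.sum(perms <= i_obs))
    else:
        exceed = int(np.sum(np.abs(perms - perms.mean()) >= abs(i_obs - perms.mean())))
    p = (1 + exceed) / (1 + n_permutations)
    return StatResult(
        statistic=float(i_obs), p_value=float(p), method="global_morans_i",
        extras={"null_mean": float(perms.mean()), "null_sd": float(perms.std()),
                "expected_i": -1.0 / (n - 1), "n_permutations": n_permutations},
    )


def local_morans_i(
    values: np.ndarray,
    neighbors: list[list[int]],
    weights: list[np.ndarray] | None = None,
    n_permutations: int = 999,
    alpha: float = 0.002,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str], list[set]]:
    """Anselin Local Moran's I with conditional permutation inference.

    Returns per-unit ``(I_i, pseudo_p, quadrant)`` plus the list of
    clusters: contiguous groups of significant high-high cells at
    ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 units")
    zc = x - x.mean()
    if np.allclose(zc, 0):
        raise ValueError("constant field: Moran's I undefined")
    if weights is None:
        weights = row_standardize(neighbors)
    m2 = float(zc @ zc) / n
    lag = np.array([
        float(wt @ zc[np.asarray(nb)]) if len(nb) else 0.0
        for nb, wt in zip(neighbors, weights)
    ])
    local_i = zc / m2 * lag

    rng = np.random.default_rng(seed)
    pseudo_p = np.ones(n)
    others_all = np.arange(n)
    for i, (nb, wt) in enumerate(zip(neighbors, weights)):
        k = len(nb)
        if k == 0:
            continue
        pool = np.delete(others_all, i)
        draws = np.empty(n_permutations)
        zi = zc[i] / m2
        for t in range(n_permutations):
            sel = rng.choice(pool, size=k, replace=False)
            draws[t] = zi * float(wt @ zc[sel])
        obs = local_i[i]
        if obs >= draws.mean():
            exceed = int(np.sum(draws >= obs))
        else:
            exceed = int(np.sum(draws <= obs))
        pseudo_p[i] = (1 + exceed) / (1 + n_permutations)

    quadrant = []
    for i in range(n):
        if pseudo_p[i] >= alpha:
            quadrant.append("not-significant")
        elif zc[i] >= 0 and lag[i] >= 0:
            quadrant.append("high-high")
        elif zc[i] < 0 and lag[i] < 0:
            quadrant.append("low-low")
        elif zc[i] >= 0:
            quadrant.append("high-low")
        else:
            quadrant.append("low-high")

    hh = {i for i, q in enumerate(quadrant) if q == "high-high"}
    clusters: list[set] = []
    seen: set[int] = set()
    for i in sorted(hh):
        if i in seen:
            continue
        comp = {i}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in neighbors[j]:
                if k in hh and k not in comp:
                    comp.add(k)
                    frontier.append(k)
        seen |= comp
        clusters.append(comp)
    return local_i, pseudo_p, quadrant, clusters


# --------------------------------------------------------------- rank tests
def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney_u(sample_a, sample_b, mode: str = "auto",
                   exact_limit: int = 200_000) -> StatResult:
    """Mann-Whitney U via midranks; exact two-sided p by full enumeration of
    rank assignments when feasible, otherwise a tie- and continuity-corrected
    normal approximation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sp_stats.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n], n)

    if mode == "exact" or (mode == "auto" and math.comb(n + m, n) <= exact_limit):
        center = n * m / 2
        d_obs = abs(u_obs - center)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            u = _u_from_ranks(ranks[list(combo)], n)
            total += 1
            if abs(u - center) >= d_obs - 1e-9:
                count += 1
        p = count / total
        method = "mann_whitney_u_exact"
    else:
        mu = n * m / 2
        # tie correction on the variance
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n + m) * (n + m - 1))
        sigma2 = n * m / 12 * ((n + m + 1) - tie_term)
        sigma = math.sqrt(sigma2) if sigma2 > 0 else float("nan")
        z = (abs(u_obs - mu) - 0.5) / sigma if sigma > 0 else 0.0
        p = 2 * sp_stats.norm.sf(max(z, 0.0))
        p = min(p, 1.0)
        method = "mann_whitney_u_normal"
    return StatResult(statistic=u_obs, p_value=float(p), method=method,
                      extras={"n": n, "m": m})


def spearman_rho(x, y, exact_n: int = 8) -> StatResult:
    """Spearman rank correlation; exact permutation p for n <= ``exact_n``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    if np.allclose(rx, rx[0]) or np.allclose(ry, ry[0]):
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n:
        count = 0
        total = 0
        zx = (rx - rx.mean()) / rx.std()
        zy = (ry - ry.mean()) / ry.std()
        for perm in itertools.permutations(range(n)):
            r = float(zx @ zy[list(perm)]) / n
            total += 1
            if abs(r) >= abs(rho) - 1e-9:
                count += 1
        p = count / total
        method = "spearman_exact"
    else:
        t = rho * math.sqrt((n - 2) / max(1 - rho ** 2, 1e-12))
        p = 2 * sp_stats.t.sf(abs(t), df=n - 2)
        method = "spearman_t_approx"
    return StatResult(statistic=rho, p_value=float(p), method=method, extras={"n": n})


# ------------------------------------------------------------- coastal rules
def assign_catchments(
    deposit_points: list[Point],
    catchments: list,
    coastline,
    forest_threshold: float = 0.0,
) -> np.ndarray:
    """Catchment id per deposit, with non-forested catchments reassigned.

    A deposit inside a forested catchment keeps it.  Deposits in catchments
    with forest fraction <= ``forest_threshold`` are handed to the forested
    catchment whose outlet is nearest *along the coastline* to their own
    catchment's outlet.
    """
    forested = [c for c in catchments if c.forest_fraction > forest_threshold]
    if not forested:
        raise ValueError("no forested catchment available for assignment")
    coastal_pos = {c.id: coastline.project(c.outlet) for c in catchments}
    forested_pos = np.array([coastal_pos[c.id] for c in forested])
    forested_ids = np.array([c.id for c in forested])
    tree = STRtree([c.polygon for c in catchments])
    out = np.empty(len(deposit_points), dtype=int)
    for i, pt in enumerate(deposit_points):
        hits = tree.query(pt, predicate="intersects")
        if len(hits) == 0:
            hits = [int(tree.nearest(pt))]
        own = catchments[int(hits[0])]
        if own.forest_fraction > forest_threshold:
            out[i] = own.id
        else:
            d = np.abs(forested_pos - coastal_pos[own.id])
            out[i] = forested_ids[int(np.argmin(d))]
    return out


@dataclass
class DistanceDecayResult:
    distances_km: np.ndarray        # per-deposit distance to nearest mouth
    curve_distance_km: np.ndarray   # sorted distances
    curve_fraction: np.ndarray      # cumulative area fraction

    def fraction_within(self, radius_km: float) -> float:
        """Empirical (step-function) cumulative area fraction at the radius."""
        if len(self.curve_distance_km) == 0:
            return float("nan")
        k = int(np.searchsorted(self.curve_distance_km, radius_km, side="right"))
        return 0.0 if k == 0 else float(self.curve_fraction[k - 1])


def distance_decay(deposit_points: list[Point], areas_m2, mouth_points: list[Point]) -> DistanceDecayResult:
    """Distance to the nearest river mouth and the cumulative-cover curve.

    Distances are straight-line in the projected plane; the curve is the
    area-weighted cumulative fraction of driftwood cover versus distance.
    """
    if not mouth_points:
        raise ValueError("need at least one river mouth")
    pts = np.array([[p.x, p.y] for p in deposit_points], dtype=float).reshape(-1, 2)
    mouths = np.array([[p.x, p.y] for p in mouth_points], dtype=float)
    if len(pts) == 0:
        return DistanceDecayResult(np.empty(0), np.empty(0), np.empty(0))
    d = np.sqrt(((pts[:, None, :] - mouths[None, :, :]) ** 2).sum(axis=2)).min(axis=1) / 1000.0
    areas = np.asarray(areas_m2, dtype=float)
    order = np.argsort(d)
    cum = np.cumsum(areas[order])
    frac = cum / cum[-1]
    return DistanceDecayResult(distances_km=d, curve_distance_km=d[order], curve_fraction=frac)
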
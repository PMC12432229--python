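"""Synthetic Arctic coastal landscapes with known driftwood ground truth.

The generator emulates the statistical structure that the mapping pipeline
assumes, so every downstream stage (compositing, segmentation, multi-year
fusion, hotspot statistics, evaluation) can be exercised end-to-end with a
known answer:

* a straight coastline with a sandy beach band, vegetated uplands, river
  channels draining at configurable mouth positions, and a gentle DEM;
* driftwood deposits placed along the coast with an exponential
  distance-decay from the nearest forested river mouth (default scale
  112 km, which puts ~83% of deposits within 200 km);
* lognormal deposit sizes that differ by setting — deposits in coastal
  clusters near mouths are larger on average (defaults 1,551 m^2 vs
  1,031 m^2 background, deltaic 1,024 m^2) — plus sub-pixel individual
  "logs" that only an aerial-resolution product can resolve;
* inter-annual remobilization: a configurable fraction of deposits is
  transient, appearing (with freshly drawn geometry) in only a subset of
  years, so multi-year fusion has something to reject;
* multi-scene rendering per year with per-scene radiometric gain/offset
  jitter, exercising histogram matching, plus jitter-free coarse reference
  and fine aerial renders.

Everything lives in one projected metric coordinate system; geometry is
shapely, rasters are :class:`~driftwood.raster.MultibandRaster`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import LineString, Point, Polygon, box, mapping
from shapely import affinity

from .raster import GridSpec, MultibandRaster, block_mean, make_grid, rasterize

# class-map codes
WATER, SAND, VEGETATION, DRIFTWOOD, INFRASTRUCTURE = 0, 1, 2, 3, 4
CLASS_NAMES = ["water", "sand", "vegetation", "driftwood", "infrastructure"]

#: per-class band means (B, G, R, NIR), surface-reflectance scale.
#: Driftwood is separable from sand mainly by its lower NIR, but the gap is
#: comparable to the default noise sd so segmentation is non-trivial.
DEFAULT_SPECTRA = {
    WATER: (0.06, 0.08, 0.07, 0.02),
    SAND: (0.18, 0.22, 0.26, 0.30),
    VEGETATION: (0.04, 0.08, 0.06, 0.40),
    DRIFTWOOD: (0.11, 0.13, 0.16, 0.20),
    INFRASTRUCTURE: (0.20, 0.20, 0.21, 0.18),
}

#: lognormal size parameters per deposit setting: (mean m^2, sd m^2).
DEFAULT_SIZES = {
    "deltaic": (1024.0, 2075.0),
    "coastal": (1551.0, 5132.0),
    "background": (1031.0, 2165.0),
    "log": (30.0, 25.0),
}


class ConfigError(ValueError):
    """Raised for invalid landscape configurations."""


@dataclass
class LandscapeConfig:
    """All knobs of the synthetic landscape and its rendering."""

    extent_m: tuple[float, float] = (1500.0, 1500.0)
    pixel_size_m: float = 3.0            # satellite grid
    aerial_pixel_size_m: float = 0.5
    reference_pixel_size_m: float = 30.0
    n_years: int = 3
    n_scenes_per_year: int = 2
    #: (x position in m, forested flag) per river mouth
    river_mouths: list[tuple[float, bool]] = field(default_factory=lambda: [(750.0, True)])
    decay_scale_km: float = 112.0
    cluster_radius_km: float = 15.0
    #: concentration of the within-cluster deposits near the mouth; the
    #: mixture keeps the marginal distance law exactly Exponential(decay
    #: scale) beyond the cluster radius (memorylessness)
    cluster_inner_scale_km: float = 5.0
    delta_radius_km: float = 2.0
    size_lognormal_params: dict = field(default_factory=lambda: dict(DEFAULT_SIZES))
    cluster_density_per_km2: float = 0.85
    background_density_per_km2: float = 0.16
    #: explicit per-mouth deposit count; overrides the density-derived count
    n_deposits_per_mouth: int | None = None
    log_fraction: float = 0.0            # extra sub-pixel logs per deposit
    remobilization_prob: float = 0.25
    shore_fraction: float = 0.3          # fraction of extent height that is sea
    beach_width_m: float = 150.0
    river_halfwidth_m: float = 15.0
    include_infrastructure: bool = True
    spectra: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    noise_sd: float = 0.02
    gain_jitter_sd: float = 0.05
    offset_jitter_sd: float = 0.01
    scene_overlap_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ConfigError("extent must be positive")
        for name in ("pixel_size_m", "aerial_pixel_size_m", "reference_pixel_size_m"):
            px = getattr(self, name)
            if px <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.decay_scale_km <= 0:
            raise ConfigError("decay_scale_km must be positive")
        if not 0 <= self.remobilization_prob <= 1:
            raise ConfigError("remobilization_prob must be in [0, 1]")
        if self.n_years < 1 or self.n_scenes_per_year < 1:
            raise ConfigError("n_years and n_scenes_per_year must be >= 1")
        wants_deposits = (
            self.cluster_density_per_km2 > 0
            or self.background_density_per_km2 > 0
            or (self.n_deposits_per_mouth or 0) > 0
        )
        if wants_deposits and not self.river_mouths:
            raise ConfigError("deposits requested but no river mouths configured")

    @property
    def shore_y(self) -> float:
        return self.extent_m[1] * self.shore_fraction

    def satellite_grid(self) -> GridSpec:
        w, h = self.extent_m
        return make_grid((0.0, 0.0, w, h), self.pixel_size_m)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spectra"] = {CLASS_NAMES[k]: list(v) for k, v in self.spectra.items()}
        d["size_lognormal_params"] = {k: list(v) for k, v in self.size_lognormal_params.items()}
        d["river_mouths"] = [[x, bool(f)] for x, f in self.river_mouths]
        return d


@dataclass
class TruthDeposit:
    """One ground-truth driftwood deposit (or individual log)."""

    id: int
    setting: str                  # deltaic | coastal | background | log
    mouth_id: int
    distance_km: float
    area_m2: float
    persistent: bool
    years: tuple[int, ...]
    cluster: bool
    geometry_by_year: dict[int, Polygon]

    def geometry(self, year: int | None = None) -> Polygon:
        if year is None:
            year = self.years[0]
        return self.geometry_by_year[year]


@dataclass
class Catchment:
    id: int
    polygon: Polygon
    forest_fraction: float
    outlet: Point


@dataclass
class SceneTruth:
    """Ground truth for one synthetic landscape."""

    config: LandscapeConfig
    dem: MultibandRaster
    water_mask_per_year: list[np.ndarray]
    class_map_per_year: list[np.ndarray]
    deposits: list[TruthDeposit]
    catchments: list[Catchment]
    infrastructure: list
    river_mouth_points: list[Point]
    coastline: LineString

    def deposits_in_year(self, year: int) -> list[TruthDeposit]:
        return [d for d in self.deposits if year in d.years]

    def stable_deposits(self, min_year_fraction: float = 0.6) -> list[TruthDeposit]:
        """Deposits present in at least ``min_year_fraction`` of years."""
        n = self.config.n_years
        return [d for d in self.deposits if len(d.years) / n >= min_year_fraction]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a target mean/sd."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _deposit_polygon(x: float, y: float, area: float, rng: np.random.Generator) -> Polygon:
    """Berm (elongated shoreline-parallel ellipse) or mat (compact blob)."""
    berm = rng.random() < 0.5
    ratio = rng.uniform(3.0, 6.0) if berm else rng.uniform(1.0, 1.6)
    # pi * a * b = area with a = ratio * b
    b = np.sqrt(area / (np.pi * ratio))
    a = ratio * b
    circle = Point(x, y).buffer(1.0, quad_segs=16)
    ellipse = affinity.scale(circle, a, b)
    angle = rng.normal(0.0, 5.0)  # roughly shoreline-parallel
    return affinity.rotate(ellipse, angle, origin=(x, y))


def _log_polygon(x: float, y: float, area: float, rng: np.random.Generator) -> Polygon:
    """A single stranded log: thin elongated rectangle."""
    width = rng.uniform(0.6, 1.2)
    length = max(area / width, 2.0)
    poly = box(x - length / 2, y - width / 2, x + length / 2, y + width / 2)
    return affinity.rotate(poly, rng.uniform(-20, 20), origin=(x, y))


def generate_landscape(config: LandscapeConfig) -> SceneTruth:
    """Build the full vector + raster ground truth for one landscape.

    Deterministic for a fixed ``config.seed``.  Deposit distances from their
    mouth are Exponential(``decay_scale_km``) along the coast (truncated to
    the extent); sizes are lognormal per setting; a fraction
    ``1 - remobilization_prob`` of deposits persists through all years,
    the rest appear (re-placed) in a random strict subset of years.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.extent_m
    shore_y = config.shore_y
    grid = config.satellite_grid()

    mouths = [Point(mx, shore_y) for mx, _ in config.river_mouths]
    forested = [bool(f) for _, f in config.river_mouths]
    coastline = LineString([(0, shore_y), (w, shore_y)])

    catchments = _make_catchments(config, rng)
    infrastructure = _make_infrastructure(config)
    forest_by_mouth = {c.id: c.forest_fraction for c in catchments}
    deposits = _place_deposits(config, rng, forest_by_mouth)

    dem = _make_dem(config, grid, rng)
    water = _water_mask(config, grid)
    water_per_year = [water.copy() for _ in range(config.n_years)]
    class_maps = [
        _class_map(config, grid, water, deposits, infrastructure, year)
        for year in range(config.n_years)
    ]

    return SceneTruth(
        config=config,
        dem=dem,
        water_mask_per_year=water_per_year,
        class_map_per_year=class_maps,
        deposits=deposits,
        catchments=catchments,
        infrastructure=infrastructure,
        river_mouth_points=mouths,
        coastline=coastline,
    )


def _make_catchments(config: LandscapeConfig, rng: np.random.Generator) -> list[Catchment]:
    w, h = config.extent_m
    shore_y = config.shore_y
    xs = sorted(range(len(config.river_mouths)), key=lambda i: config.river_mouths[i][0])
    bounds = [0.0]
    for a, b in zip(xs, xs[1:]):
        bounds.append((config.river_mouths[a][0] + config.river_mouths[b][0]) / 2)
    bounds.append(w)
    out = []
    for k, i in enumerate(xs):
        mx, forested = config.river_mouths[i]
        frac = float(rng.uniform(0.4, 0.9)) if forested else 0.0
        out.append(
            Catchment(
                id=i,
                polygon=box(bounds[k], shore_y, bounds[k + 1], h),
                forest_fraction=frac,
                outlet=Point(mx, shore_y),
            )
        )
    return sorted(out, key=lambda c: c.id)


def _make_infrastructure(config: LandscapeConfig) -> list:
    if not config.include_infrastructure:
        return []
    w, h = config.extent_m
    road_y = config.shore_y + config.beach_width_m + 60.0
    if road_y >= h:
        return []
    road = LineString([(0, road_y), (w, road_y)]).buffer(6.0)
    b1 = box(0.1 * w, road_y + 20, 0.1 * w + 30, road_y + 50)
    b2 = box(0.8 * w, road_y + 20, 0.8 * w + 30, road_y + 50)
    return [g for g in (road, b1, b2) if g.within(box(0, 0, w, h))] or [road]


def _place_deposits(
    config: LandscapeConfig,
    rng: np.random.Generator,
    forest_by_mouth: dict[int, float] | None = None,
) -> list[TruthDeposit]:
    w, h = config.extent_m
    shore_y = config.shore_y
    band_lo = shore_y + 8.0
    band_hi = min(shore_y + config.beach_width_m - 8.0, h - 8.0)
    if band_hi <= band_lo:
        band_lo, band_hi = shore_y + 2.0, min(shore_y + 20.0, h - 2.0)

    forested_mouths = [(i, mx) for i, (mx, f) in enumerate(config.river_mouths) if f]
    deposits: list[TruthDeposit] = []
    if not forested_mouths:
        return deposits

    scale_m = config.decay_scale_km * 1000.0
    cluster_m = config.cluster_radius_km * 1000.0
    delta_m = config.delta_radius_km * 1000.0
    params = {k: _lognormal_params(*v) for k, v in config.size_lognormal_params.items()}

    did = 0
    for mouth_id, mx in forested_mouths:
        n = config.n_deposits_per_mouth
        if n is None:
            # expected count calibrated so the realized density inside the
            # cluster radius matches cluster_density_per_km2 over a 1 km-deep
            # coastal band, under the exponential placement law
            coast_reach = min(cluster_m, max(mx, w - mx))
            p_cluster = 1.0 - np.exp(-coast_reach / scale_m)
            band_depth_km = (band_hi - band_lo) / 1000.0
            cluster_area = 2 * (coast_reach / 1000.0) * max(band_depth_km, 0.05)
            lam = config.cluster_density_per_km2 * cluster_area / max(p_cluster, 1e-9)
            # driftwood supply scales with the catchment's boreal forest
            # cover (0.65 = mean of the default forest-fraction draw), so
            # cover-vs-forest correlation is a property of the truth
            if forest_by_mouth is not None:
                lam *= forest_by_mouth.get(mouth_id, 0.65) / 0.65
            n = int(rng.poisson(lam))
        channel_margin = config.river_halfwidth_m + 12.0
        mouth_xs = [m for m, _ in config.river_mouths]

        inner_m = config.cluster_inner_scale_km * 1000.0
        p_cluster_mix = 1.0 - np.exp(-cluster_m / scale_m)

        def _draw_x() -> tuple[float, float] | None:
            # distance along the coast with the cluster/tail mixture: the
            # within-cluster mass (= F(rc) of the exponential) is drawn
            # from a short-scale truncated exponential, the remainder from
            # rc + Exp(scale); by memorylessness the marginal law equals
            # Exponential(scale) at and beyond the cluster radius.  The
            # draw is repeated until it lands inside the extent and clear
            # of river channels.
            for _attempt in range(200):
                if rng.random() < p_cluster_mix:
                    u = rng.random()
                    d = -inner_m * np.log1p(-u * (1.0 - np.exp(-cluster_m / inner_m)))
                else:
                    d = cluster_m + rng.exponential(scale_m)
                x = mx + d * (1 if rng.random() < 0.5 else -1)
                if 0 < x < w and all(abs(x - m2) > channel_margin for m2 in mouth_xs):
                    return d, x
            return None

        def _draw_y(area: float) -> float:
            # keep the footprint's across-shore half-width out of the sea
            half = min(np.sqrt(area / np.pi), (band_hi - band_lo) / 2)
            return rng.uniform(min(band_lo + half, band_hi - 1.0), band_hi)

        for _ in range(n):
            drawn = _draw_x()
            if drawn is None:
                continue
            d, x = drawn
            cluster = d <= cluster_m
            if d <= delta_m:
                setting = "deltaic"
            elif cluster:
                setting = "coastal"
            else:
                setting = "background"
            mu, sg = params[setting]
            area = float(rng.lognormal(mu, sg))
            y = _draw_y(area)
            persistent = rng.random() >= config.remobilization_prob
            if persistent or config.n_years == 1:
                years = tuple(range(config.n_years))
                geom = _deposit_polygon(x, y, area, rng)
                geoms = {yy: geom for yy in years}
            else:
                k = int(rng.integers(1, config.n_years))
                years = tuple(sorted(rng.choice(config.n_years, size=k, replace=False).tolist()))
                geoms = {}
                for yy in years:
                    xx = float(np.clip(x + rng.normal(0, 2000.0), 1, w - 1))
                    geoms[yy] = _deposit_polygon(xx, _draw_y(area), area, rng)
            deposits.append(
                TruthDeposit(
                    id=did,
                    setting=setting,
                    mouth_id=mouth_id,
                    distance_km=d / 1000.0,
                    area_m2=area,
                    persistent=persistent,
                    years=years,
                    cluster=cluster,
                    geometry_by_year=geoms,
                )
            )
            did += 1
        # sub-pixel individual logs, resolvable only in the aerial render
        n_logs = int(round(config.log_fraction * n))
        mu, sg = params["log"]
        for _ in range(n_logs):
            drawn = _draw_x()
            if drawn is None:
                continue
            d, x = drawn
            area = float(rng.lognormal(mu, sg))
            geom = _log_polygon(x, rng.uniform(band_lo, band_hi), area, rng)
            years = tuple(range(config.n_years))
            deposits.append(
                TruthDeposit(
                    id=did,
                    setting="log",
                    mouth_id=mouth_id,
                    distance_km=d / 1000.0,
                    area_m2=area,
                    persistent=True,
                    years=years,
                    cluster=d <= cluster_m,
                    geometry_by_year={yy: geom for yy in years},
                )
            )
            did += 1
    return deposits


def _make_dem(config: LandscapeConfig, grid: GridSpec, rng: np.random.Generator) -> MultibandRaster:
    rr, cc = np.meshgrid(np.arange(grid.rows), np.arange(grid.cols), indexing="ij")
    _, ys = grid.cell_centers(rr, cc)
    elev = np.maximum(ys - config.shore_y, 0.0) * 0.005
    from scipy.ndimage import zoom

    bumps = rng.normal(0.0, 0.3, size=(max(grid.rows // 16, 1), max(grid.cols // 16, 1)))
    bumps = zoom(bumps, (grid.rows / bumps.shape[0], grid.cols / bumps.shape[1]), order=1)
    bumps = bumps[: grid.rows, : grid.cols]
    if bumps.shape != (grid.rows, grid.cols):
        bumps = np.pad(bumps, ((0, grid.rows - bumps.shape[0]), (0, grid.cols - bumps.shape[1])), mode="edge")
    elev = (elev + np.where(elev > 0, bumps, 0.0)).astype(np.float32)
    return MultibandRaster(data=elev[None], grid=grid, band_names=["dem"])


def _water_geoms(config: LandscapeConfig) -> list[Polygon]:
    w, h = config.extent_m
    sea = box(0, 0, w, config.shore_y)
    rivers = [
        box(mx - config.river_halfwidth_m, config.shore_y, mx + config.river_halfwidth_m, h)
        for mx, _ in config.river_mouths
    ]
    return [sea, *rivers]


def _water_mask(config: LandscapeConfig, grid: GridSpec) -> np.ndarray:
    return rasterize(_water_geoms(config), grid, dtype=np.uint8).astype(bool)


def _class_map(
    config: LandscapeConfig,
    grid: GridSpec,
    water: np.ndarray,
    deposits: list[TruthDeposit],
    infrastructure: list,
    year: int,
) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(grid.rows), np.arange(grid.cols), indexing="ij")
    _, ys = grid.cell_centers(rr, cc)
    cmap = np.full((grid.rows, grid.cols), VEGETATION, dtype=np.uint8)
    beach = (ys >= config.shore_y) & (ys < config.shore_y + config.beach_width_m)
    cmap[beach] = SAND
    cmap[water] = WATER
    if infrastructure:
        rasterize(infrastructure, grid, values=INFRASTRUCTURE, out=cmap, dtype=np.uint8)
    geoms = [d.geometry_by_year[year] for d in deposits if year in d.years]
    if geoms:
        rasterize(geoms, grid, values=DRIFTWOOD, out=cmap, dtype=np.uint8)
    return cmap


# ------------------------------------------------------------------ renders
def _render_class_map(
    cmap: np.ndarray,
    spectra: dict,
    noise_sd: float,
    rng: np.random.Generator | None,
    gain: np.ndarray | None = None,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    lut = np.zeros((max(spectra) + 1, 4), dtype=np.float64)
    for cls, vals in spectra.items():
        lut[cls] = vals[:4]
    img = lut[cmap].transpose(2, 0, 1)  # (4, rows, cols)
    if gain is not None:
        img = img * gain[:, None, None] + offset[:, None, None]
    if noise_sd > 0 and rng is not None:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32)


def render_scenes(truth: SceneTruth, year: int, config: LandscapeConfig | None = None) -> list[MultibandRaster]:
    """Render the per-year imagery as overlapping scene strips.

    Each scene covers a vertical strip of the tile; adjacent strips overlap
    by ``scene_overlap_fraction`` of a strip width and the union covers the
    extent.  Each scene carries its own multiplicative gain and additive
    offset per band plus Gaussian pixel noise.
    """
    config = config or truth.config
    if not 0 <= year < config.n_years:
        raise ConfigError(f"year {year} outside 0..{config.n_years - 1}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001, year]))
    grid = config.satellite_grid()
    cmap = truth.class_map_per_year[year]
    n = config.n_scenes_per_year
    base = grid.cols / n
    pad = int(np.ceil(base * config.scene_overlap_fraction / 2)) if n > 1 else 0
    scenes = []
    for i in range(n):
        c0 = max(int(np.floor(i * base)) - pad, 0)
        c1 = min(int(np.ceil((i + 1) * base)) + pad, grid.cols)
        gain = 1.0 + rng.normal(0.0, config.gain_jitter_sd, size=4)
        offset = rng.normal(0.0, config.offset_jitter_sd, size=4)
        img = _render_class_map(cmap[:, c0:c1], config.spectra, config.noise_sd, rng, gain, offset)
        sub = GridSpec(
            x0=grid.x0 + c0 * grid.px, y0=grid.y0, px=grid.px, py=grid.py,
            rows=grid.rows, cols=c1 - c0,
        )
        scenes.append(MultibandRaster(data=img, grid=sub, band_names=["blue", "green", "red", "nir"]))
    return scenes


def render_reference(truth: SceneTruth, config: LandscapeConfig | None = None) -> MultibandRaster:
    """Coarse, jitter-free reference composite (histogram-matching target).

    Rendered noiselessly at the satellite grid and block-averaged to the
    reference pixel size, mimicking a coarse-sensor medoid composite.
    """
    config = config or truth.config
    grid = config.satellite_grid()
    factor = int(round(config.reference_pixel_size_m / config.pixel_size_m))
    img = _render_class_map(truth.class_map_per_year[0], config.spectra, 0.0, None)
    fine = MultibandRaster(data=img, grid=grid, band_names=["blue", "green", "red", "nir"])
    if factor <= 1:
        return fine
    rows = grid.rows - grid.rows % factor
    cols = grid.cols - grid.cols % factor
    if (rows, cols) != (grid.rows, grid.cols):
        # trim to a block-divisible region; a histogram-matching target does
        # not need full coverage
        sub = GridSpec(x0=grid.x0, y0=grid.y0, px=grid.px, py=grid.py, rows=rows, cols=cols)
        fine = MultibandRaster(data=fine.data[:, :rows, :cols], grid=sub,
                               band_names=list(fine.band_names))
    return block_mean(fine, factor)


def render_aerial(truth: SceneTruth, config: LandscapeConfig | None = None) -> MultibandRaster:
    """High-resolution 4-band render resolving individual logs.

    The class map is re-rasterized at the aerial pixel size, so deposits
    below the satellite minimum mapping unit appear here.
    """
    config = config or truth.config
    if config.aerial_pixel_size_m >= config.pixel_size_m:
        raise ConfigError("aerial pixel size must be finer than the satellite grid")
    w, h = config.extent_m
    grid = make_grid((0.0, 0.0, w, h), config.aerial_pixel_size_m)
    water = _water_mask(config, grid)
    cmap = _class_map(config, grid, water, truth.deposits, truth.infrastructure, 0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7002]))
    img = _render_class_map(cmap, config.spectra, config.noise_sd / 2, rng)
    return MultibandRaster(data=img, grid=grid, band_names=["blue", "green", "red", "nir"])


def aerial_class_map(truth: SceneTruth, config: LandscapeConfig | None = None) -> np.ndarray:
    """Categorical aerial-grid rasterization of the year-0 truth."""
    config = config or truth.config
    w, h = config.extent_m
    grid = make_grid((0.0, 0.0, w, h), config.aerial_pixel_size_m)
    water = _water_mask(config, grid)
    return _class_map(config, grid, water, truth.deposits, truth.infrastructure, 0)


# ------------------------------------------------------------------ truth I/O
def write_truth(truth: SceneTruth, out_dir) -> None:
    """Persist the truth: rasters as TIFF, vectors as GeoJSON, manifest YAML."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.dem.write(str(out / "dem.tif"))
    grid = truth.config.satellite_grid()
    for y, (wm, cm) in enumerate(zip(truth.water_mask_per_year, truth.class_map_per_year)):
        MultibandRaster(data=wm.astype(np.float32)[None], grid=grid, band_names=["water"]).write(
            str(out / f"water_year{y}.tif")
        )
        MultibandRaster(data=cm.astype(np.float32)[None], grid=grid, band_names=["class"]).write(
            str(out / f"classes_year{y}.tif")
        )
    _write_geojson(
        out / "deposits.geojson",
        [
            {
                "geometry": d.geometry(),
                "properties": {
                    "id": d.id, "setting": d.setting, "mouth_id": d.mouth_id,
                    "distance_km": d.distance_km, "area_m2": d.area_m2,
                    "persistent": d.persistent, "years": list(d.years), "cluster": d.cluster,
                },
            }
            for d in truth.deposits
        ],
    )
    _write_geojson(
        out / "catchments.geojson",
        [
            {"geometry": c.polygon, "properties": {"id": c.id, "forest_fraction": c.forest_fraction,
                                                   "outlet": [c.outlet.x, c.outlet.y]}}
            for c in truth.catchments
        ],
    )
    _write_geojson(out / "infrastructure.geojson", [{"geometry": g, "properties": {}} for g in truth.infrastructure])
    _write_geojson(
        out / "river_mouths.geojson",
        [{"geometry": p, "properties": {"forested": bool(f[1])}}
         for p, f in zip(truth.river_mouth_points, truth.config.river_mouths)],
    )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"config": truth.config.to_dict()}, fh)


def _plain(value):
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def _write_geojson(path, features: list[dict]) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": {k: _plain(v) for k, v in f["properties"].items()},
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)
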
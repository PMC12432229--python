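"""End-to-end orchestration: simulate -> composite -> train -> predict ->
fuse -> analyze -> evaluate.

Each stage draws its randomness from a seed derived by hashing the stage
name with the global seed, so stages are independently reproducible and a
rerun with the same configuration reproduces the deterministic artifacts
exactly.  Stage outputs are written under the run directory as plain
formats (TIFF, GeoJSON, CSV, JSON, YAML) together with a provenance
manifest.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import compositing, deposit_extraction, evaluation, segmentation, spatial_stats
from .bayes import best_bayes_compare, bayes_correlation
from .config import RunConfig, save_config, stage_seed
from .raster import MultibandRaster
from .synthetic_scene import (
    DRIFTWOOD,
    SceneTruth,
    generate_landscape,
    render_reference,
    render_scenes,
    write_truth,
)

log = logging.getLogger("driftwood")


@dataclass
class PipelineResult:
    config: RunConfig
    truth: SceneTruth
    composites: list[MultibandRaster]
    train_report: segmentation.TrainReport
    annual_masks: list[np.ndarray]
    deposits: list[deposit_extraction.Deposit]
    removal_log: list[dict]
    cells: list[spatial_stats.HexCell]
    stats: dict = field(default_factory=dict)
    eval_report: evaluation.EvalReport | None = None
    durations: dict = field(default_factory=dict)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _timed(durations: dict, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            durations[stage] = round(time.time() - self.t0, 2)
            if exc is None:
                log.info("stage %s: done in %.1fs", stage, durations[stage])
                return False
            raise StageFailure(stage, exc) from exc

    return _Ctx()


def simulate(config: RunConfig) -> SceneTruth:
    land = config.landscape
    if land.seed == 0:
        from dataclasses import replace

        land = replace(land, seed=stage_seed(config.seed, "simulate"))
    return generate_landscape(land)


def build_composites(truth: SceneTruth, config: RunConfig) -> tuple[list[MultibandRaster], list[np.ndarray]]:
    """Annual 5-band composites and matching driftwood label rasters."""
    land = truth.config
    reference = render_reference(truth, land)
    grid = land.satellite_grid()
    composites, labels = [], []
    for year in range(land.n_years):
        scenes = render_scenes(truth, year, land)
        comp = compositing.build_annual_composite(scenes, reference, tile_grid=grid)
        comp = compositing.stack_elevation(comp, truth.dem)
        lab = (truth.class_map_per_year[year] == DRIFTWOOD).astype(np.float32)
        if config.upsample_factor > 1:
            comp = segmentation.upsample_bicubic(comp, config.upsample_factor)
            lab_r = MultibandRaster(data=lab[None], grid=grid)
            lab = segmentation.upsample_bicubic(lab_r, config.upsample_factor, labels=True).data[0]
        composites.append(comp)
        labels.append(lab)
    return composites, labels


def train_model(composites, labels, config: RunConfig):
    """60/20/20 area split on a rectangular partition of the tile, patch
    sampling from the year-0 composite, Tversky training."""
    seed = stage_seed(config.seed, "train")
    comp, lab = composites[0], labels[0]
    rows, cols = comp.shape
    patch = config.model.patch_size
    # partition the tile into full-height vertical strips: every strip
    # crosses sea, beach and uplands, so each split sees all surface types
    n_strips = max(min(config.n_areas, cols // patch), 1)
    areas = []
    for j in range(n_strips):
        c0, c1 = cols * j // n_strips, cols * (j + 1) // n_strips
        if c1 - c0 >= patch and rows >= patch:
            areas.append((0, c0, rows, c1))
    if not areas:
        areas = [(0, 0, rows, cols)]
    ids = list(range(len(areas)))
    tr_ids, va_ids, te_ids = segmentation.split_areas(ids, config.split_fractions, seed)
    if not tr_ids or not va_ids:
        tr_ids = ids[: max(len(ids) - 1, 1)]
        va_ids = ids[len(tr_ids):] or ids[-1:]
    n = config.n_train_patches
    # oversample, then prefer patches that contain driftwood: the class is
    # sparse, and all-background batches stall the Tversky optimization
    cand = segmentation.sample_patches(comp, lab, 3 * n, patch, seed + 1, [areas[i] for i in tr_ids])
    pos = [p for p in cand if p[1].any()]
    neg = [p for p in cand if not p[1].any()]
    # half the set contains driftwood, half is pure background (beach,
    # water, vegetation): the balance matters — too few negatives and the
    # model calls the whole beach band driftwood
    n_pos = min(len(pos), max(n // 2, 1))
    tr = pos[:n_pos] + neg[: n - n_pos]
    if not tr:
        tr = cand[:n]
    va = segmentation.sample_patches(comp, lab, max(n // 4, 4), patch, seed + 2, [areas[i] for i in va_ids])
    # light augmentation: flips double the training set
    aug = []
    for k, pair in enumerate(tr):
        aug += segmentation.augment(pair, ["hflip"] if k % 2 else ["vflip"], seed + 3 + k)
    tr = tr + aug
    model = segmentation.build_unet(config.model)
    manifest = {"train_areas": tr_ids, "val_areas": va_ids, "test_areas": te_ids}
    report = segmentation.train(model, tr, va, config.model, split_manifest=manifest)
    return model, report


def predict_years(model, composites, config: RunConfig) -> list[np.ndarray]:
    masks = []
    for comp in composites:
        binary, _ = segmentation.predict_tiled(model, comp, config.model)
        masks.append(binary)
    return masks


def fuse_and_filter(truth: SceneTruth, annual_masks, config: RunConfig):
    """Multi-year fusion at the satellite grid, then the mapping filters."""
    land = truth.config
    grid = land.satellite_grid()
    if annual_masks[0].shape != (grid.rows, grid.cols):
        # predictions on the upsampled grid: vote back to the native grid
        f = annual_masks[0].shape[0] // grid.rows
        annual_masks = [
            m[: grid.rows * f, : grid.cols * f]
            .reshape(grid.rows, f, grid.cols, f)
            .mean(axis=(1, 3)) >= 0.5
            for m in annual_masks
        ]
    prob = deposit_extraction.presence_probability(list(annual_masks))
    deposits = deposit_extraction.extract_deposits(prob, grid, config.t_presence, config.t_shape)
    water_mask = deposit_extraction.build_water_mask(truth.water_mask_per_year, config.water_persistence)
    kept, removal_log = deposit_extraction.filter_deposits(
        deposits, water_mask, truth.infrastructure, config.max_water_fraction, config.max_holes
    )
    deposit_extraction.year_support(kept, list(annual_masks))
    return kept, removal_log


def analyze(truth: SceneTruth, deposits, config: RunConfig) -> tuple[list, dict]:
    """Hex aggregation, hotspots, group comparisons, catchment and
    distance-decay statistics.  Degenerate inputs yield flagged entries
    instead of raising."""
    seed = stage_seed(config.seed, "analyze")
    land = truth.config
    w, h = land.extent_m
    cells = spatial_stats.make_hex_grid((0, 0, w, h), config.hex_cell_m)
    geoms = [d.geometry for d in deposits]
    spatial_stats.aggregate_to_grid(geoms, cells)
    stats: dict = {"flags": []}
    values = np.array([c.cover_fraction for c in cells])
    neighbors = [c.neighbors for c in cells]

    if len(cells) >= 3 and values.std() > 0:
        gm = spatial_stats.global_morans_i(values, neighbors, n_permutations=config.n_permutations, seed=seed)
        stats["global_morans_i"] = gm
        li, pp, quad, clusters = spatial_stats.local_morans_i(
            values, neighbors, n_permutations=config.n_permutations, alpha=config.lisa_alpha, seed=seed + 1
        )
        for c, (i_val, p_val, q) in zip(cells, zip(li, pp, quad)):
            c.local_i, c.pseudo_p, c.quadrant = float(i_val), float(p_val), q
        stats["n_hotspot_clusters"] = len(clusters)
        cluster_cells = set().union(*clusters) if clusters else set()
    else:
        stats["flags"].append("no_spatial_variance")
        cluster_cells = set()

    # deposit cluster membership: centroid inside a hotspot cluster cell,
    # falling back to the truth's distance-based clusters when the grid is
    # too small for LISA hotspots (single-tile desk runs)
    from shapely.strtree import STRtree

    if deposits:
        if cluster_cells:
            tree = STRtree([cells[i].polygon for i in sorted(cluster_cells)])
            for d in deposits:
                d.cluster_member = bool(len(tree.query(d.geometry.centroid, predicate="within")))
        stats["n_deposits"] = len(deposits)
        stats["total_area_m2"] = float(sum(d.area_m2 for d in deposits))
        stats["mean_area_m2"] = stats["total_area_m2"] / len(deposits)
    else:
        stats["flags"].append("no_deposits")
        stats["n_deposits"] = 0
        stats["total_area_m2"] = 0.0
        return cells, stats

    # in-cluster vs out-of-cluster deposit sizes
    in_sizes = [d.area_m2 for d in deposits if d.cluster_member]
    out_sizes = [d.area_m2 for d in deposits if not d.cluster_member]
    if len(in_sizes) >= 2 and len(out_sizes) >= 2:
        stats["size_mwu"] = spatial_stats.mann_whitney_u(in_sizes, out_sizes)
        stats["size_best"] = best_bayes_compare(in_sizes, out_sizes, seed=seed + 2)
    else:
        stats["flags"].append("cluster_groups_too_small")

    # catchment assignment and forest-cover correlation
    centroids = [d.geometry.centroid for d in deposits]
    try:
        ids = spatial_stats.assign_catchments(centroids, truth.catchments, truth.coastline)
        for d, cid in zip(deposits, ids):
            d.catchment_id = int(cid)
        per_catch = {}
        for d in deposits:
            per_catch.setdefault(d.catchment_id, 0.0)
            per_catch[d.catchment_id] += d.area_m2
        forested = [c for c in truth.catchments if c.forest_fraction > 0]
        fracs = [c.forest_fraction for c in forested]
        covers = [per_catch.get(c.id, 0.0) for c in forested]
        if len(forested) >= 3:
            stats["forest_cover_spearman"] = spatial_stats.spearman_rho(fracs, covers)
            stats["forest_cover_bayes"] = bayes_correlation(fracs, covers, seed=seed + 3)
        else:
            stats["flags"].append("too_few_catchments_for_correlation")
    except ValueError as err:
        stats["flags"].append(f"catchment_assignment: {err}")

    # distance decay from forested mouths
    mouths = [p for p, (_, f) in zip(truth.river_mouth_points, land.river_mouths) if f]
    if mouths:
        areas = np.array([d.area_m2 for d in deposits])
        decay = spatial_stats.distance_decay(centroids, areas, mouths)
        for d, dist in zip(deposits, decay.distances_km):
            d.distance_to_mouth_km = float(dist)
        stats["distance_decay"] = decay
        stats["fraction_within_200km"] = decay.fraction_within(200.0)
        # declining cover with distance: area per distance bin vs distance
        dists = decay.distances_km
        n_bins = min(10, max(len(deposits) // 5, 3))
        edges = np.linspace(0.0, float(dists.max()) + 1e-9, n_bins + 1)
        which = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
        bin_cover = np.bincount(which, weights=areas, minlength=n_bins)
        bin_mid = 0.5 * (edges[:-1] + edges[1:])
        if len(np.unique(bin_mid)) >= 3 and bin_cover.std() > 0:
            stats["distance_cover_spearman"] = spatial_stats.spearman_rho(bin_mid, bin_cover)
    return cells, stats


def evaluate(truth: SceneTruth, deposits, config: RunConfig) -> evaluation.EvalReport:
    """Compare mapped deposits against the aerial-resolution reference:
    the simulator's year-0 truth geometries (including sub-pixel logs)."""
    ref_geoms = [d.geometry(0) for d in truth.deposits if 0 in d.years]
    pred_geoms = [d.geometry for d in deposits]
    w, h = truth.config.extent_m
    return evaluation.grid_compare(pred_geoms, ref_geoms, config.eval_cell_m, extent=(0, 0, w, h))


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    """Execute all stages, persisting artifacts and provenance under
    ``out_dir``.  A stage failure aborts with the stage name; artifacts of
    completed stages remain on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    durations: dict = {}

    with _timed(durations, "simulate"):
        truth = simulate(config)
        write_truth(truth, out / "truth")
    with _timed(durations, "composite"):
        composites, labels = build_composites(truth, config)
        for y, comp in enumerate(composites):
            comp.write(str(out / f"composite_year{y}.tif"))
    with _timed(durations, "train"):
        model, report = train_model(composites, labels, config)
    with _timed(durations, "predict"):
        annual_masks = predict_years(model, composites, config)
    with _timed(durations, "fuse"):
        deposits, removal_log = fuse_and_filter(truth, annual_masks, config)
        _write_deposits(out / "deposits.geojson", deposits)
        pd.DataFrame(removal_log, columns=["id", "rule", "value"]).to_csv(
            out / "removal_log.csv", index=False
        )
    with _timed(durations, "analyze"):
        cells, stats = analyze(truth, deposits, config)
        _write_stats(out, cells, stats)
    with _timed(durations, "evaluate"):
        eval_report = evaluate(truth, deposits, config)
        with open(out / "eval_report.json", "w") as fh:
            json.dump(_jsonable(eval_report.to_dict()), fh, indent=1)

    save_config(config, out / "run_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "stage_seeds": {s: stage_seed(config.seed, s) for s in
                                ("simulate", "train", "analyze")},
                "durations_s": durations,
                "n_deposits": len(deposits),
                "train_val_iou": report.val_iou[-1] if report.val_iou else None,
            },
            fh, indent=1,
        )
    return PipelineResult(
        config=config, truth=truth, composites=composites, train_report=report,
        annual_masks=annual_masks, deposits=deposits, removal_log=removal_log,
        cells=cells, stats=stats, eval_report=eval_report, durations=durations,
    )


def _write_deposits(path, deposits) -> None:
    features = []
    for d in deposits:
        features.append({
            "type": "Feature",
            "geometry": mapping(d.geometry),
            "properties": {
                "id": d.id, "area_m2": d.area_m2, "hole_count": d.hole_count,
                "water_fraction": d.water_fraction, "year_support": d.year_support,
                "distance_to_mouth_km": None if math.isnan(d.distance_to_mouth_km) else d.distance_to_mouth_km,
                "catchment_id": d.catchment_id, "setting": d.setting,
                "cluster_member": d.cluster_member,
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _write_stats(out: Path, cells, stats: dict) -> None:
    rows = [{
        "id": c.id, "cover_fraction": c.cover_fraction, "deposit_count": c.deposit_count,
        "density_per_km2": c.density_per_km2, "local_i": c.local_i,
        "pseudo_p": c.pseudo_p, "quadrant": c.quadrant,
    } for c in cells]
    pd.DataFrame(rows).to_csv(out / "hex_cells.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(_jsonable(stats), fh, indent=1)


def _jsonable(obj):
    from .spatial_stats import DistanceDecayResult, StatResult

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, StatResult):
        return _jsonable(obj.__dict__)
    if isinstance(obj, DistanceDecayResult):
        return {"n": len(obj.distances_km)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
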
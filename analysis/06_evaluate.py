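"""Evaluate the mapped deposits against the aerial-resolution reference.

Loads the filtered deposit set from script 04 and compares it with the
simulator's year-0 truth geometries (which include individual logs below
the satellite minimum mapping unit) on a 512 m grid: r^2 and slope of the
per-cell regression, overall relative bias, and the size-stratified bias
that shows where the omitted area sits.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
from _common import DESK_DIR, desk_config
from shapely.geometry import shape

from driftwood.evaluation import grid_compare
from driftwood.pipeline import simulate


def main() -> None:
    cfg = desk_config()
    truth = simulate(cfg)
    path = DESK_DIR / "deposits.geojson"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 04_fuse.py first")
    with open(path) as fh:
        pred_geoms = [shape(f["geometry"]) for f in json.load(fh)["features"]]
    ref_geoms = [d.geometry(0) for d in truth.deposits if 0 in d.years]

    w, h = cfg.landscape.extent_m
    rep = grid_compare(pred_geoms, ref_geoms, cfg.eval_cell_m, extent=(0, 0, w, h))

    print(f"compared {len(pred_geoms)} mapped vs {len(ref_geoms)} reference deposits "
          f"on a {cfg.eval_cell_m:.0f} m grid ({rep.n_cells} cells)")
    print(f"r2 = {rep.r_squared:.3f}, slope = {rep.slope:.3f} "
          f"(through origin: {rep.slope_through_origin:.3f})")
    print(f"relative bias: {rep.relative_bias_percent:+.2f}% overall, "
          f"{rep.relative_bias_excluding_small_percent:+.2f}% excluding deposits < "
          f"{rep.small_edge_m2:.0f} m2")
    for lab, bias in rep.per_bin_bias_percent.items():
        share = rep.per_bin_ref_share[lab]
        bias_s = "n/a" if np.isnan(bias) else f"{bias:+.1f}%"
        print(f"  size bin {lab} m2: bias {bias_s} (share of reference area {share:.1%})")
    with open(DESK_DIR / "eval_report.json", "w") as fh:
        json.dump(rep.to_dict(), fh, indent=1, default=float)
    print(f"wrote {DESK_DIR / 'eval_report.json'}")


if __name__ == "__main__":
    main()
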
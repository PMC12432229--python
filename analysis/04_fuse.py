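"""Fuse the annual prediction masks into stable deposits and filter them.

Loads the annual masks from script 03, computes the per-pixel presence
probability, extracts deposits with the 0.6 presence / 0.5 shape
thresholds, applies the water-coverage, infrastructure and hole-count
filters, and writes the final deposit set (GeoJSON) plus the removal log.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from _common import DESK_DIR, desk_config
from shapely.geometry import mapping

from driftwood.pipeline import _write_deposits, fuse_and_filter, simulate
from driftwood.raster import MultibandRaster


def main() -> None:
    cfg = desk_config()
    truth = simulate(cfg)
    masks = []
    for y in range(cfg.landscape.n_years):
        path = DESK_DIR / f"mask_year{y}.tif"
        if not path.exists():
            raise SystemExit(f"{path} missing - run 03_train_predict.py first")
        masks.append(MultibandRaster.read(str(path)).data[0] >= 0.5)

    deposits, removal_log = fuse_and_filter(truth, masks, cfg)
    _write_deposits(DESK_DIR / "deposits.geojson", deposits)
    pd.DataFrame(removal_log, columns=["id", "rule", "value"]).to_csv(
        DESK_DIR / "removal_log.csv", index=False)

    areas = np.array([d.area_m2 for d in deposits])
    print(f"fused deposits: {len(deposits)} kept, {len(removal_log)} removed "
          f"({pd.Series([r['rule'] for r in removal_log]).value_counts().to_dict() if removal_log else {}})")
    if len(areas):
        print(f"total mapped area {areas.sum():,.0f} m2, mean deposit "
              f"{areas.mean():,.0f} m2, largest {areas.max():,.0f} m2")
        print(f"mean year-support of kept deposits: "
              f"{np.mean([d.year_support for d in deposits]):.2f}")
    print(f"wrote deposits.geojson and removal_log.csv to {DESK_DIR}")


if __name__ == "__main__":
    main()
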
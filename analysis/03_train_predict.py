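"""Train the dilated U-Net on the desk tile and predict all years.

Samples training/validation patches from a 60/20/20 split of vertical
training strips, optimizes the Tversky loss, reports per-epoch losses and
validation IoU, then runs tiled prediction (2% patch overlap, union rule)
over each annual composite.  Annual binary masks are written as TIFF for
the fusion step.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
from _common import DESK_DIR, desk_config

from driftwood.pipeline import build_composites, predict_years, simulate, train_model
from driftwood.raster import MultibandRaster
from driftwood.segmentation import confusion_metrics
from driftwood.synthetic_scene import DRIFTWOOD


def main() -> None:
    cfg = desk_config()
    truth = simulate(cfg)
    composites, labels = build_composites(truth, cfg)
    model, report = train_model(composites, labels, cfg)

    print(f"model: {model.parameter_count():,} parameters, dilation rate "
          f"{cfg.model.dilation_rate}, Tversky alpha/beta "
          f"{cfg.model.tversky_alpha}/{cfg.model.tversky_beta}")
    for e, (tl, vl, vi) in enumerate(zip(report.train_loss, report.val_loss, report.val_iou)):
        print(f"  epoch {e}: train loss {tl:.3f}, val loss {vl:.3f}, val IoU {vi:.3f}")
    print(f"best epoch {report.best_epoch}; validation metrics: "
          f"{ {k: round(v, 4) for k, v in report.test_metrics.items() if k != 'undefined'} }")

    masks = predict_years(model, composites, cfg)
    grid = cfg.landscape.satellite_grid()
    for y, m in enumerate(masks):
        iou = confusion_metrics(m, truth.class_map_per_year[y] == DRIFTWOOD).iou
        print(f"year {y}: {int(m.sum())} driftwood pixels predicted, full-tile IoU {iou:.3f}")
        MultibandRaster(data=m.astype(np.float32)[None], grid=grid,
                        band_names=["driftwood"]).write(str(DESK_DIR / f"mask_year{y}.tif"))
    with open(DESK_DIR / "train_report.json", "w") as fh:
        json.dump({"train_loss": report.train_loss, "val_loss": report.val_loss,
                   "val_iou": report.val_iou, "best_epoch": report.best_epoch,
                   "test_metrics": report.test_metrics,
                   "split_manifest": report.split_manifest}, fh, indent=1)
    print(f"wrote annual masks and train_report.json to {DESK_DIR}")


if __name__ == "__main__":
    main()
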
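"""Per-pixel driftwood segmentation with a dilated U-Net.

The classifier is a U-Net-style encoder/decoder over the 4 spectral bands
plus elevation: dilated 3x3 convolutions (rate 2 by default) in the encoder
enlarge the receptive field without extra parameters, batch normalization
follows every convolution, and the Tversky loss

    L = 1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps)

with soft counts handles the extreme class imbalance of sparse driftwood
against background (``beta > alpha`` penalizes missed wood more than false
alarms).  Training data is bicubically upsampled imagery, randomly sampled
square patches with geometric/photometric augmentation, and a 60/20/20
area split.  Prediction runs on overlapping tiles (2% overlap) with an OR
("any hit wins") merge rule in the overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as sk_filters
from skimage import transform as sk_transform

from . import nn
from .raster import GridSpec, MultibandRaster

AUGMENT_OPS = (
    "vflip",
    "hflip",
    "random_crop",
    "linear_contrast",
    "piecewise_affine",
    "perspective",
    "gamma_contrast",
    "normalize",
    "gaussian_blur",
)

GEOMETRIC_OPS = {"vflip", "hflip", "random_crop", "piecewise_affine", "perspective"}


@dataclass
class SegModelConfig:
    input_bands: int = 5
    depth: int = 2                 # encoder levels
    base_filters: int = 8
    dilation_rate: int = 2
    tversky_alpha: float = 0.3     # false-positive weight
    tversky_beta: float = 0.7      # false-negative weight
    smoothing_epsilon: float = 1.0
    patch_size: int = 64
    overlap_fraction: float = 0.02
    learning_rate: float = 3e-3
    epochs: int = 8
    batch_size: int = 8
    steps_per_epoch: int = 25
    binarization_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tversky_alpha <= 0 or self.tversky_beta <= 0:
            raise ValueError("tversky alpha and beta must be positive")
        if not 0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.patch_size % 2:
            raise ValueError("patch_size must be even")


@dataclass
class TrainReport:
    train_loss: list[float]
    val_loss: list[float]
    val_iou: list[float]
    best_epoch: int
    test_metrics: dict
    split_manifest: dict
    seed: int


# ----------------------------------------------------------------- resampling
def upsample_bicubic(raster: MultibandRaster, factor: float, labels: bool = False) -> MultibandRaster:
    """Scale a raster's resolution up by ``factor``.

    Continuous imagery is interpolated bicubically; label/mask rasters use
    nearest neighbour so class semantics survive.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1:
        return raster.copy()
    g = raster.grid
    rows, cols = int(round(g.rows * factor)), int(round(g.cols * factor))
    target = GridSpec(x0=g.x0, y0=g.y0, px=g.px * g.cols / cols, py=g.py * g.rows / rows,
                      rows=rows, cols=cols)
    order = 0 if labels else 3
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    src_r = (rr + 0.5) / factor - 0.5
    src_c = (cc + 0.5) / factor - 0.5
    out = np.empty((raster.n_bands, rows, cols), dtype=np.float32)
    for b in range(raster.n_bands):
        out[b] = ndimage.map_coordinates(raster.data[b].astype(np.float64),
                                         np.stack([src_r, src_c]), order=order, mode="nearest")
    return MultibandRaster(data=out, grid=target, crs=raster.crs,
                           nodata=raster.nodata, band_names=list(raster.band_names))


# ----------------------------------------------------------------- splitting
def split_areas(area_ids: list, fractions: tuple[float, float, float], seed: int) -> tuple[list, list, list]:
    """Deterministic 3-way split of area ids by the given fractions."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(area_ids)
    nonzero = sum(f > 0 for f in fractions)
    if n < nonzero:
        raise ValueError(f"{n} areas cannot fill {nonzero} nonempty splits")
    # largest-remainder apportionment so sizes sum to n
    raw = np.array(fractions) * n
    sizes = np.floor(raw).astype(int)
    order = np.argsort(-(raw - sizes))
    for i in range(n - sizes.sum()):
        sizes[order[i]] += 1
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(n))
    ids = [area_ids[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return ids[:a], ids[a:b], ids[b:]


def sample_patches(
    composite: MultibandRaster,
    labels: np.ndarray,
    n: int,
    patch_size: int,
    seed: int,
    areas: list[tuple[int, int, int, int]] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random aligned (image, mask) patches fully inside the given areas.

    ``areas`` are (row0, col0, row1, col1) windows; default is the full
    raster.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows, cols = composite.shape
    if areas is None:
        areas = [(0, 0, rows, cols)]
    for k, (r0, c0, r1, c1) in enumerate(areas):
        if r1 - r0 < patch_size or c1 - c0 < patch_size:
            raise ValueError(f"area {k} ({r0},{c0},{r1},{c1}) smaller than patch size {patch_size}")
    out = []
    for _ in range(n):
        r0, c0, r1, c1 = areas[rng.integers(len(areas))]
        rr = int(rng.integers(r0, r1 - patch_size + 1))
        cc = int(rng.integers(c0, c1 - patch_size + 1))
        img = composite.data[:, rr: rr + patch_size, cc: cc + patch_size].copy()
        msk = labels[rr: rr + patch_size, cc: cc + patch_size].astype(np.float32).copy()
        out.append((img, msk))
    return out


# ---------------------------------------------------------------- augmentation
def _warp_pair(img, mask, tform):
    warped = np.stack([
        sk_transform.warp(img[b].astype(np.float64), tform, order=1, mode="edge")
        for b in range(img.shape[0])
    ]).astype(np.float32)
    wmask = sk_transform.warp(mask.astype(np.float64), tform, order=0, mode="edge").astype(np.float32)
    return warped, wmask


def piecewise_affine(img, mask, displacement_sd: float, rng: np.random.Generator):
    """Piecewise-affine warp on a 4x4 control grid, applied to both layers."""
    h, w = mask.shape
    src_pts = np.stack(np.meshgrid(np.linspace(0, w - 1, 4), np.linspace(0, h - 1, 4)), axis=-1).reshape(-1, 2)
    dst_pts = src_pts + rng.normal(0.0, displacement_sd, size=src_pts.shape)
    tform = sk_transform.PiecewiseAffineTransform()
    tform.estimate(dst_pts, src_pts)
    return _warp_pair(img, mask, tform)


def perspective(img, mask, corner_sd: float, rng: np.random.Generator):
    h, w = mask.shape
    src_pts = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    dst_pts = src_pts + rng.normal(0.0, corner_sd, size=src_pts.shape)
    tform = sk_transform.ProjectiveTransform()
    tform.estimate(dst_pts, src_pts)
    return _warp_pair(img, mask, tform)


def apply_augmentation(op: str, img: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    """One augmentation; geometric ops warp both layers (mask via nearest
    neighbour), photometric ops leave the mask untouched."""
    if op == "vflip":
        return img[:, ::-1].copy(), mask[::-1].copy()
    if op == "hflip":
        return img[:, :, ::-1].copy(), mask[:, ::-1].copy()
    if op == "random_crop":
        h, w = mask.shape
        ch, cw = int(h * 0.8), int(w * 0.8)
        r = int(rng.integers(0, h - ch + 1))
        c = int(rng.integers(0, w - cw + 1))
        sub = img[:, r: r + ch, c: c + cw]
        smk = mask[r: r + ch, c: c + cw]
        up = np.stack([sk_transform.resize(sub[b], (h, w), order=3, mode="edge", anti_aliasing=False)
                       for b in range(img.shape[0])]).astype(np.float32)
        upm = sk_transform.resize(smk, (h, w), order=0, mode="edge", anti_aliasing=False).astype(np.float32)
        return up, upm
    if op == "piecewise_affine":
        return piecewise_affine(img, mask, displacement_sd=2.0, rng=rng)
    if op == "perspective":
        return perspective(img, mask, corner_sd=3.0, rng=rng)
    if op == "linear_contrast":
        a = rng.uniform(0.8, 1.2)
        mean = img.mean(axis=(1, 2), keepdims=True)
        return ((img - mean) * a + mean).astype(np.float32), mask
    if op == "gamma_contrast":
        gamma = rng.uniform(0.7, 1.4)
        lo = img.min(axis=(1, 2), keepdims=True)
        hi = img.max(axis=(1, 2), keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        scaled = np.clip((img - lo) / span, 0, 1)
        return (scaled ** gamma * span + lo).astype(np.float32), mask
    if op == "normalize":
        mean = img.mean(axis=(1, 2), keepdims=True)
        sd = img.std(axis=(1, 2), keepdims=True)
        return ((img - mean) / np.where(sd > 0, sd, 1.0)).astype(np.float32), mask
    if op == "gaussian_blur":
        sigma = rng.uniform(0.3, 1.0)
        return np.stack([sk_filters.gaussian(img[b], sigma=sigma, preserve_range=True)
                         for b in range(img.shape[0])]).astype(np.float32), mask
    raise ValueError(f"unknown augmentation op: {op}")


def augment(pair: tuple[np.ndarray, np.ndarray], ops: list[str], seed: int):
    """One augmented pair per requested op, deterministic per seed."""
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op: {op}")
    rng = np.random.default_rng(seed)
    img, mask = pair
    return [apply_augmentation(op, img, mask, rng) for op in ops]


# ------------------------------------------------------------------- loss
def tversky_loss(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.3,
                 beta: float = 0.7, epsilon: float = 1.0) -> float:
    loss, _ = tversky_loss_grad(pred, truth, alpha, beta, epsilon)
    return loss


def tversky_loss_grad(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.3,
                      beta: float = 0.7, epsilon: float = 1.0) -> tuple[float, np.ndarray]:
    """Tversky loss and its gradient with respect to the probabilities."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    p = pred.astype(np.float64)
    t = truth.astype(np.float64)
    tp = (p * t).sum()
    fp = (p * (1 - t)).sum()
    fn = ((1 - p) * t).sum()
    denom = tp + alpha * fp + beta * fn + epsilon
    loss = 1.0 - (tp + epsilon) / denom
    # d(tp)/dp = t, d(fp)/dp = 1-t, d(fn)/dp = -t
    ddenom = t + alpha * (1 - t) - beta * t
    grad = -(t * denom - (tp + epsilon) * ddenom) / denom ** 2
    return float(loss), grad.astype(np.float32)


# ------------------------------------------------------------------- model
class _ConvBlock(nn.Sequential):
    def __init__(self, c_in: int, c_out: int, dilation: int, rng) -> None:
        super().__init__(
            nn.Conv2d(c_in, c_out, 3, dilation, rng), nn.BatchNorm2d(c_out), nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, dilation, rng), nn.BatchNorm2d(c_out), nn.ReLU(),
        )


class UNet:
    """Encoder/decoder with skip connections; encoder convolutions dilated."""

    def __init__(self, config: SegModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, d = config.base_filters, config.depth
        dil = config.dilation_rate
        self.enc = []
        c = config.input_bands
        for lvl in range(d):
            self.enc.append((_ConvBlock(c, f * 2 ** lvl, dil, rng), nn.MaxPool2d()))
            c = f * 2 ** lvl
        self.bottleneck = _ConvBlock(c, f * 2 ** d, 1, rng)
        self.dec = []
        c = f * 2 ** d
        for lvl in reversed(range(d)):
            skip_c = f * 2 ** lvl
            self.dec.append((nn.UpsampleNearest2(), _ConvBlock(c + skip_c, skip_c, 1, rng)))
            c = skip_c
        self.head = nn.Conv2d(c, 1, kernel=1, rng=rng)
        self.sigmoid = nn.Sigmoid()
        self.norm_mean = np.zeros(config.input_bands, dtype=np.float32)
        self.norm_sd = np.ones(config.input_bands, dtype=np.float32)

        self.params, self.grads = [], []
        for blk, _ in self.enc:
            self.params += blk.params
            self.grads += blk.grads
        self.params += self.bottleneck.params
        self.grads += self.bottleneck.grads
        for _, blk in self.dec:
            self.params += blk.params
            self.grads += blk.grads
        self.params += self.head.params
        self.grads += self.head.grads

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def fit_normalization(self, images: np.ndarray) -> None:
        self.norm_mean = images.mean(axis=(0, 2, 3)).astype(np.float32)
        self.norm_sd = (images.std(axis=(0, 2, 3)) + 1e-6).astype(np.float32)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean[None, :, None, None]) / self.norm_sd[None, :, None, None]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.config.input_bands:
            raise ValueError(f"expected {self.config.input_bands} bands, got {x.shape[1]}")
        div = 2 ** self.config.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div}; pad to "
                f"({-(-x.shape[2] // div) * div}, {-(-x.shape[3] // div) * div})"
            )
        x = self._normalize(x).astype(np.float32)
        self._skips = []
        for blk, pool in self.enc:
            x = blk.forward(x, train)
            self._skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for (up, blk), skip in zip(self.dec, reversed(self._skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        logits = self.head.forward(x, train)
        return self.sigmoid.forward(logits, train)[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        dy = self.sigmoid.backward(dprob[:, None])
        dy = self.head.backward(dy)
        dskips = []
        for (up, blk), sc in zip(reversed(self.dec), reversed(self._skip_channels)):
            dcat = blk.backward(dy)
            dskips.append(dcat[:, :sc])
            dy = up.backward(dcat[:, sc:])
        dy = self.bottleneck.backward(dy)
        for (blk, pool), dskip in zip(reversed(self.enc), reversed(dskips)):
            dy = pool.backward(dy)
            dy = blk.backward(dy + dskip)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def state(self) -> list[np.ndarray]:
        bn_state = []
        for lay in self._all_layers():
            if isinstance(lay, nn.BatchNorm2d):
                bn_state += [lay.running_mean.copy(), lay.running_var.copy()]
        return [p.copy() for p in self.params] + bn_state

    def load_state(self, state: list[np.ndarray]) -> None:
        np_ = len(self.params)
        for p, s in zip(self.params, state[:np_]):
            p[...] = s
        it = iter(state[np_:])
        for lay in self._all_layers():
            if isinstance(lay, nn.BatchNorm2d):
                lay.running_mean = next(it).copy()
                lay.running_var = next(it).copy()

    def _all_layers(self):
        for blk, pool in self.enc:
            yield from blk.layers
            yield pool
        yield from self.bottleneck.layers
        for up, blk in self.dec:
            yield up
            yield from blk.layers
        yield self.head


def build_unet(config: SegModelConfig) -> UNet:
    """Construct the model with seeded initial weights."""
    return UNet(config)


class TrainingDiverged(RuntimeError):
    pass


def train(
    model: UNet,
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    config: SegModelConfig | None = None,
    split_manifest: dict | None = None,
) -> TrainReport:
    """Adam optimization of the Tversky loss with best-checkpoint retention.

    Deterministic for a fixed seed.  Aborts with :class:`TrainingDiverged`
    if the loss becomes non-finite.
    """
    config = config or model.config
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    imgs = np.stack([p[0] for p in train_pairs])
    masks = np.stack([p[1] for p in train_pairs])
    model.fit_normalization(imgs)
    vimgs = np.stack([p[0] for p in val_pairs])
    vmasks = np.stack([p[1] for p in val_pairs])
    opt = nn.Adam(model.params, model.grads, lr=config.learning_rate)

    train_losses, val_losses, val_ious = [], [], []
    best = (np.inf, -1, None)
    for epoch in range(config.epochs):
        epoch_losses = []
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(train_pairs), size=min(config.batch_size, len(train_pairs)))
            xb, tb = imgs[idx], masks[idx]
            prob = model.forward(xb, train=True)
            loss, dprob = tversky_loss_grad(prob, tb, config.tversky_alpha,
                                            config.tversky_beta, config.smoothing_epsilon)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dprob)
            opt.step()
            epoch_losses.append(loss)
        train_losses.append(float(np.mean(epoch_losses)))

        vprob = _batched_predict(model, vimgs)
        vloss = tversky_loss(vprob, vmasks, config.tversky_alpha,
                             config.tversky_beta, config.smoothing_epsilon)
        vbin = vprob >= config.binarization_threshold
        m = confusion_metrics(vbin, vmasks >= 0.5)
        val_losses.append(float(vloss))
        val_ious.append(m.iou)
        if vloss < best[0]:
            best = (vloss, epoch, model.state())

    if best[2] is not None:
        model.load_state(best[2])
    vprob = _batched_predict(model, vimgs)
    final = confusion_metrics(vprob >= config.binarization_threshold, vmasks >= 0.5)
    return TrainReport(
        train_loss=train_losses,
        val_loss=val_losses,
        val_iou=val_ious,
        best_epoch=best[1],
        test_metrics=final.to_dict(),
        split_manifest=split_manifest or {},
        seed=config.seed,
    )


def _batched_predict(model: UNet, imgs: np.ndarray, batch: int = 8) -> np.ndarray:
    out = [model.predict(imgs[i: i + batch]) for i in range(0, len(imgs), batch)]
    return np.concatenate(out, axis=0)


# ------------------------------------------------------------------ inference
def patch_origins(size: int, patch: int, overlap_fraction: float) -> list[int]:
    """Tile origins: stride = patch - floor(overlap_fraction * patch), with a
    final tile clamped to the boundary so coverage is complete."""
    if size <= patch:
        return [0]
    stride = patch - int(np.floor(overlap_fraction * patch))
    origins = list(range(0, size - patch + 1, stride))
    if origins[-1] != size - patch:
        origins.append(size - patch)
    return origins


def predict_tiled(model: UNet, composite: MultibandRaster,
                  config: SegModelConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Tiled inference over a full composite.

    Returns ``(binary, probability)``.  Overlap pixels are positive if any
    contributing patch calls them positive at the binarization threshold
    (union rule); the probability raster keeps the per-pixel maximum for
    diagnostics.
    """
    config = config or model.config
    if composite.n_bands != config.input_bands:
        raise ValueError(f"composite has {composite.n_bands} bands, model wants {config.input_bands}")
    rows, cols = composite.shape
    patch = config.patch_size
    binary = np.zeros((rows, cols), dtype=bool)
    prob = np.zeros((rows, cols), dtype=np.float32)
    pr, pc = max(patch - rows, 0), max(patch - cols, 0)
    data = composite.data
    if pr or pc:
        data = np.pad(data, ((0, 0), (0, pr), (0, pc)), mode="edge")
    for r0 in patch_origins(rows, patch, config.overlap_fraction):
        for c0 in patch_origins(cols, patch, config.overlap_fraction):
            tile = data[:, r0: r0 + patch, c0: c0 + patch]
            p = model.predict(tile[None])[0]
            p = p[: rows - r0, : cols - c0]
            win = (slice(r0, r0 + p.shape[0]), slice(c0, c0 + p.shape[1]))
            binary[win] |= p >= config.binarization_threshold
            prob[win] = np.maximum(prob[win], p)
    return binary, prob


# ------------------------------------------------------------------- metrics
@dataclass
class ConfusionMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    iou: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "iou": self.iou, "undefined": self.undefined,
        }


def confusion_metrics(pred: np.ndarray, truth: np.ndarray,
                      valid: np.ndarray | None = None) -> ConfusionMetrics:
    """Accuracy, sensitivity, specificity and IoU from binary rasters.

    Ratios with empty denominators are NaN and listed in ``undefined``.
    """
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    p = pred.astype(bool)
    t = truth.astype(bool)
    if valid is not None:
        p, t = p[valid], t[valid]
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    n = tp + tn + fp + fn
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        accuracy=ratio(tp + tn, n, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        iou=ratio(tp, tp + fp + fn, "iou"),
        undefined=undefined,
    )
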
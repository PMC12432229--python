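import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftwood.segmentation import (
    AUGMENT_OPS,
    SegModelConfig,
    augment,
    build_unet,
    confusion_metrics,
    patch_origins,
    piecewise_affine,
    predict_tiled,
    sample_patches,
    split_areas,
    train,
    tversky_loss,
    tversky_loss_grad,
    upsample_bicubic,
)


class TestUpsample:
    def test_factor_one_identity(self, make_raster):
        r = make_raster(np.random.default_rng(0).random((2, 6, 6)))
        out = upsample_bicubic(r, 1)
        assert np.array_equal(out.data, r.data)

    def test_constant_scales_dimensions(self, make_raster):
        r = make_raster(np.full((1, 4, 4), 2.5))
        out = upsample_bicubic(r, 3)
        assert out.shape == (12, 12)
        assert np.allclose(out.data, 2.5, atol=1e-6)
        assert out.grid.px == pytest.approx(r.grid.px / 3)

    def test_linear_ramp_preserved(self, make_raster):
        ramp = np.tile(np.arange(40, dtype=float), (40, 1))
        r = make_raster(ramp)
        out = upsample_bicubic(r, 3)
        expected = (np.arange(120) + 0.5) / 3 - 0.5
        interior = out.data[0, 60, 30:-30]
        assert np.allclose(interior, expected[30:-30], atol=1e-5)

    def test_labels_use_nearest(self, make_raster):
        lab = np.zeros((4, 4)); lab[1, 1] = 1.0
        out = upsample_bicubic(make_raster(lab), 3, labels=True)
        assert set(np.unique(out.data)) == {0.0, 1.0}
        assert out.data.sum() == 9

    def test_nonpositive_factor(self, make_raster):
        with pytest.raises(ValueError):
            upsample_bicubic(make_raster(np.zeros((1, 4, 4))), 0)


class TestSplitAreas:
    def test_60_20_20_sizes(self):
        tr, va, te = split_areas(list(range(10)), (0.6, 0.2, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)
        assert sorted(tr + va + te) == list(range(10))

    def test_deterministic(self):
        s1 = split_areas(list("abcdefgh"), (0.6, 0.2, 0.2), seed=5)
        s2 = split_areas(list("abcdefgh"), (0.6, 0.2, 0.2), seed=5)
        assert s1 == s2

    def test_all_train(self):
        tr, va, te = split_areas([1, 2, 3], (1.0, 0.0, 0.0), seed=1)
        assert sorted(tr) == [1, 2, 3] and va == [] and te == []

    def test_too_few_areas(self):
        with pytest.raises(ValueError):
            split_areas([1, 2], (0.6, 0.2, 0.2), seed=0)


class TestSamplePatches:
    def test_zero_patches(self, make_raster):
        r = make_raster(np.zeros((2, 16, 16)))
        assert sample_patches(r, np.zeros((16, 16)), 0, 8, seed=0) == []

    def test_background_labels_give_zero_masks(self, make_raster):
        r = make_raster(np.random.default_rng(1).random((2, 16, 16)))
        pairs = sample_patches(r, np.zeros((16, 16)), 5, 8, seed=0)
        assert all(m.sum() == 0 for _, m in pairs)

    def test_deterministic_corners(self, make_raster):
        r = make_raster(np.random.default_rng(2).random((1, 32, 32)))
        lab = np.arange(32 * 32).reshape(32, 32).astype(float)
        p1 = sample_patches(r, lab, 6, 8, seed=3)
        p2 = sample_patches(r, lab, 6, 8, seed=3)
        for (_, m1), (_, m2) in zip(p1, p2):
            assert np.array_equal(m1, m2)

    def test_small_area_error_names_area(self, make_raster):
        r = make_raster(np.zeros((1, 16, 16)))
        with pytest.raises(ValueError, match="area 0"):
            sample_patches(r, np.zeros((16, 16)), 1, 8, seed=0, areas=[(0, 0, 4, 4)])


class TestAugment:
    @pytest.fixture
    def pair(self):
        rng = np.random.default_rng(4)
        return rng.random((3, 16, 16)).astype(np.float32), (rng.random((16, 16)) > 0.7).astype(np.float32)

    def test_flip_is_involution(self, pair):
        img, mask = pair
        (i1, m1), = augment((img, mask), ["hflip"], seed=0)
        (i2, m2), = augment((i1, m1), ["hflip"], seed=0)
        assert np.array_equal(i2, img)
        assert np.array_equal(m2, mask)

    @pytest.mark.parametrize("op", ["linear_contrast", "gamma_contrast", "normalize", "gaussian_blur"])
    def test_photometric_ops_never_touch_mask(self, pair, op):
        img, mask = pair
        (_, m1), = augment((img, mask), [op], seed=1)
        assert np.array_equal(m1, mask)

    def test_zero_displacement_piecewise_affine_is_identity(self, pair):
        img, mask = pair
        out_img, out_mask = piecewise_affine(img, mask, displacement_sd=0.0,
                                             rng=np.random.default_rng(0))
        assert np.allclose(out_img, img, atol=1e-6)
        assert np.array_equal(out_mask, mask)

    def test_unknown_op_rejected(self, pair):
        with pytest.raises(ValueError, match="unknown"):
            augment(pair, ["solarize"], seed=0)

    def test_full_catalogue_runs(self, pair):
        out = augment(pair, list(AUGMENT_OPS), seed=2)
        assert len(out) == len(AUGMENT_OPS)
        for img, mask in out:
            assert img.shape == pair[0].shape
            assert mask.shape == pair[1].shape


class TestTverskyLoss:
    def test_perfect_prediction_zero_loss(self):
        t = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert tversky_loss(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_empty_truth_empty_pred_zero_by_epsilon(self):
        z = np.zeros((4, 4))
        assert tversky_loss(z, z, epsilon=1.0) == pytest.approx(0.0)

    def test_hand_computed_soft_counts(self):
        # TP=2, FP=1, FN=1 with alpha=0.3, beta=0.7 -> 1 - 2/3
        pred = np.array([1.0, 1.0, 1.0, 0.0])
        truth = np.array([1.0, 1.0, 0.0, 1.0])
        loss = tversky_loss(pred, truth, alpha=0.3, beta=0.7, epsilon=1e-12)
        assert loss == pytest.approx(1 / 3, abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tversky_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_alpha_beta_half_equals_dice(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((6, 6))
        truth = (rng.random((6, 6)) > 0.6).astype(float)
        tv = tversky_loss(pred, truth, alpha=0.5, beta=0.5, epsilon=1e-9)
        inter = (pred * truth).sum()
        dice = 1 - (2 * inter + 2e-9) / (pred.sum() + truth.sum() + 2e-9)
        assert tv == pytest.approx(dice, abs=1e-7)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_moving_toward_truth_never_increases_loss(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((5, 5))
        truth = (rng.random((5, 5)) > 0.5).astype(float)
        step = rng.random((5, 5)) * 0.3
        closer = pred + np.sign(truth - pred) * np.minimum(step, np.abs(truth - pred))
        l0 = tversky_loss(pred, truth, epsilon=1e-9)
        l1 = tversky_loss(closer, truth, epsilon=1e-9)
        assert l1 <= l0 + 1e-9

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(9)
        pred = rng.random((4, 4))
        truth = (rng.random((4, 4)) > 0.5).astype(float)
        _, grad = tversky_loss_grad(pred, truth, epsilon=0.5)
        i = (2, 3)
        eps = 1e-6
        up = pred.copy(); up[i] += eps
        dn = pred.copy(); dn[i] -= eps
        num = (tversky_loss(up, truth, epsilon=0.5) - tversky_loss(dn, truth, epsilon=0.5)) / (2 * eps)
        assert grad[i] == pytest.approx(num, rel=1e-4)


class TestTraining:
    def test_all_background_labels_give_empty_prediction(self, make_raster):
        rng = np.random.default_rng(0)
        cfg = SegModelConfig(input_bands=2, depth=1, base_filters=2, patch_size=16,
                             epochs=4, steps_per_epoch=15, batch_size=4,
                             learning_rate=1e-2, seed=0)
        pairs = [(rng.random((2, 16, 16)).astype(np.float32), np.zeros((16, 16), dtype=np.float32))
                 for _ in range(6)]
        model = build_unet(cfg)
        report = train(model, pairs[:4], pairs[4:], cfg)
        assert "sensitivity" in report.test_metrics["undefined"]
        prob = model.predict(pairs[0][0][None])
        assert (prob < 0.5).mean() > 0.95

    def test_empty_sets_rejected(self):
        cfg = SegModelConfig(input_bands=2, depth=1, base_filters=2, patch_size=16)
        with pytest.raises(ValueError):
            train(build_unet(cfg), [], [], cfg)


class TestPredictTiled:
    def test_patch_origins_stride_arithmetic(self):
        # 1000 px row, patch 512, 2% overlap -> stride 502, origins {0, 488}
        assert patch_origins(1000, 512, 0.02) == [0, 488]

    def test_origins_cover_every_pixel(self):
        for size, patch in [(100, 32), (129, 64), (64, 64), (40, 64)]:
            origins = patch_origins(size, patch, 0.02)
            covered = np.zeros(size, dtype=bool)
            for o in origins:
                covered[o: o + patch] = True
            assert covered.all()

    def test_constant_zero_model_empty_mask(self, make_raster):
        cfg = SegModelConfig(input_bands=2, depth=1, base_filters=2, patch_size=16)
        model = build_unet(cfg)

        class Zero:
            config = cfg

            def predict(self, x):
                return np.zeros((x.shape[0], x.shape[2], x.shape[3]), dtype=np.float32)

        binary, prob = predict_tiled(Zero(), make_raster(np.zeros((2, 40, 40))), cfg)
        assert not binary.any()
        assert prob.max() == 0

    def test_union_rule_any_patch_positive_wins(self, make_raster):
        cfg = SegModelConfig(input_bands=1, depth=1, base_filters=2, patch_size=16,
                             overlap_fraction=0.25)

        class FirstPatchOnly:
            config = cfg
            calls = 0

            def predict(self, x):
                self.calls += 1
                val = 1.0 if self.calls == 1 else 0.0
                return np.full((x.shape[0], x.shape[2], x.shape[3]), val, dtype=np.float32)

        binary, prob = predict_tiled(FirstPatchOnly(), make_raster(np.zeros((1, 16, 28))), cfg)
        # overlap pixels belong to the first (positive) and second (negative)
        # patch; union keeps them positive
        assert binary[:, :16].all()
        assert not binary[:, 16:].any()

    def test_band_mismatch(self, make_raster):
        cfg = SegModelConfig(input_bands=3, depth=1, base_filters=2, patch_size=16)
        model = build_unet(cfg)
        with pytest.raises(ValueError):
            predict_tiled(model, make_raster(np.zeros((2, 32, 32))), cfg)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        t = np.array([[1, 0], [0, 1]], dtype=bool)
        m = confusion_metrics(t, t)
        assert (m.accuracy, m.sensitivity, m.specificity, m.iou) == (1, 1, 1, 1)

    def test_hand_counts(self):
        # TP=2, FP=1, FN=1, TN=12
        truth = np.zeros(16, dtype=bool); truth[:3] = True
        pred = np.zeros(16, dtype=bool); pred[:2] = True; pred[3] = True
        m = confusion_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(12 / 13)
        assert m.accuracy == pytest.approx(14 / 16)
        assert m.iou == pytest.approx(0.5)

    def test_all_negative_truth_flags_sensitivity(self):
        m = confusion_metrics(np.zeros(4, dtype=bool), np.zeros(4, dtype=bool))
        assert "sensitivity" in m.undefined
        assert np.isnan(m.sensitivity)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_iou_bounded_by_sensitivity_and_precision(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random(30) > 0.5
        truth = rng.random(30) > 0.5
        m = confusion_metrics(pred, truth)
        tp = np.sum(pred & truth)
        if tp + np.sum(pred & ~truth) == 0 or np.isnan(m.iou) or np.isnan(m.sensitivity):
            return
        precision = tp / np.sum(pred)
        assert m.iou <= m.sensitivity + 1e-12
        assert m.iou <= precision + 1e-12
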
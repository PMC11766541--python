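"""Model architecture, DiceCE loss, augmentation and training contracts."""

import numpy as np
import pytest

from standcount.errors import ValidationError
from standcount.segmentation import (
    AugConfig,
    SegModelConfig,
    TrainConfig,
    augment,
    build_model,
    dice_ce_loss,
    predict_mask,
    train,
    _dice_ce_with_grad,
)
from standcount.synthetic_fields import FieldSpec, SegDataset, generate_dataset


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(SegModelConfig("rn18", 0.25, 64), seed=0)


class TestBuildModel:
    def test_output_shape_and_probability_range(self, tiny_model, rng):
        x = rng.integers(0, 255, (2, 64, 64, 3), dtype=np.uint8)
        prob = tiny_model.predict_proba(x)
        assert prob.shape == (2, 64, 64)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_full_width_bottleneck_is_512x16x16(self):
        model = build_model(SegModelConfig("rn18", 1.0, 512), seed=0)
        x = np.zeros((1, 512, 512, 3), dtype=np.uint8)
        xx = np.ascontiguousarray(x.astype(np.float32).transpose(0, 3, 1, 2))
        f0 = model.stem_relu.forward(
            model.stem_bn.forward(model.stem_conv.forward(xx, False), False), False)
        h = model.pool.forward(f0, False)
        for stage in model.stages:
            for block in stage:
                h = block.forward(h, False)
        assert h.shape == (1, 512, 16, 16)

    def test_parameter_counts_ordered_by_encoder_depth(self):
        counts = {
            enc: build_model(SegModelConfig(enc, 0.25, 64), seed=0).n_parameters()
            for enc in ("rn18", "rn34", "rn50")
        }
        assert counts["rn50"] > counts["rn34"] > counts["rn18"]

    def test_tile_not_divisible_by_32_rejected(self):
        with pytest.raises(ValidationError):
            SegModelConfig("rn18", 0.25, 100).validate()

    def test_save_load_roundtrip(self, tiny_model, tmp_path, rng):
        x = rng.integers(0, 255, (1, 64, 64, 3), dtype=np.uint8)
        before = tiny_model.predict_proba(x)
        tiny_model.save(tmp_path / "m.pkl")
        from standcount.segmentation import SegModel

        loaded = SegModel.load(tmp_path / "m.pkl")
        assert np.allclose(loaded.predict_proba(x), before)


class TestDiceCELoss:
    def test_perfect_hard_prediction_is_near_zero(self, rng):
        t = (rng.random((32, 32)) > 0.8).astype(np.float64)
        assert dice_ce_loss(t, t) <= 1e-3

    def test_uniform_half_on_empty_target_closed_form(self):
        n = 64 * 64
        pred = np.full((64, 64), 0.5)
        target = np.zeros((64, 64))
        expected = np.log(2) + 1.0 - 1.0 / (0.5 * n + 1.0)
        assert dice_ce_loss(pred, target) == pytest.approx(expected, abs=1e-9)
        assert dice_ce_loss(pred, target) == pytest.approx(1.693, abs=2e-3)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(1000):
            pred = rng.random((8, 8))
            target = (rng.random((8, 8)) > 0.5).astype(float)
            assert dice_ce_loss(pred, target) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((6, 6))
        t = (rng.random((6, 6)) > 0.7).astype(np.float64)
        loss, grad = _dice_ce_with_grad(logits, t)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (5, 5)]:
            lp = _dice_ce_with_grad(logits + eps * _onehot(logits.shape, idx), t)[0]
            lm = _dice_ce_with_grad(logits - eps * _onehot(logits.shape, idx), t)[0]
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice_ce_loss(np.zeros((4, 4)), np.zeros((5, 5)))


def _onehot(shape, idx):
    e = np.zeros(shape)
    e[idx] = 1.0
    return e


class TestAugment:
    def _pair(self, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        mask = np.where(rng.random((64, 64)) > 0.9, 255, 0).astype(np.uint8)
        return img, mask

    def test_identity_when_everything_disabled(self, rng):
        img, mask = self._pair(rng)
        cfg = AugConfig(rotate_deg_max=0, scale_jitter_max=0, brightness_contrast=False,
                        gamma_jitter=False, hflip=False, vflip=False, crop_px=64)
        out_img, out_mask = augment(img, mask, cfg, seed=0)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_forced_hflip_mirrors_both(self, rng):
        img, mask = self._pair(rng)
        cfg = AugConfig(rotate_deg_max=0, scale_jitter_max=0, brightness_contrast=False,
                        gamma_jitter=False, hflip=True, vflip=False, crop_px=64)
        out_img, out_mask = augment(img, mask, cfg, seed=0, force={"hflip"})
        assert np.array_equal(out_img, img[:, ::-1])
        assert np.array_equal(out_mask, mask[:, ::-1])
        assert out_mask.sum() == mask.sum()

    def test_rotation_preserves_foreground_area_approximately(self, rng):
        from standcount.field_data import rasterize_centers

        mask = rasterize_centers([(32.0, 32.0), (16.0, 48.0)], (64, 64)).pixels
        img = np.repeat(mask[:, :, None], 3, axis=2)
        cfg = AugConfig(rotate_deg_max=90, scale_jitter_max=0, brightness_contrast=False,
                        gamma_jitter=False, hflip=False, vflip=False, crop_px=64)
        # exact quarter turn: area preserved within interpolation slack
        _, out_mask = augment(img, mask, cfg, seed=0, force={"rotate90"})
        assert (out_mask > 0).sum() == pytest.approx((mask > 0).sum(), rel=0.02)
        # arbitrary angles resample the discs, so allow a little more slack
        for seed in range(5):
            _, out_mask = augment(img, mask, cfg, seed=seed)
            assert (out_mask > 0).sum() == pytest.approx((mask > 0).sum(), rel=0.06)

    def test_mask_stays_binary_under_full_recipe(self, rng):
        img, mask = self._pair(rng)
        cfg = AugConfig(crop_px=48)
        out_img, out_mask = augment(img, mask, cfg, seed=3)
        assert out_img.shape == (48, 48, 3)
        assert set(np.unique(out_mask)) <= {0, 255}


def _toy_green_dataset(n_tiles=24, size=64, seed=0):
    """Tiles where the target is exactly the green-dominant blob area."""
    specs = [FieldSpec(width_px=128, height_px=128, row_spacing_cm=45.0,
                       in_row_spacing_cm=25.0, weed_rate=0.0)]
    return generate_dataset(specs, n_per_spec=max(n_tiles // 4, 2), tile_px=size,
                            seed=seed, split_fractions=(0.75, 0.25, 0.0))


class TestTrain:
    def test_single_epoch_records_starting_learning_rate(self):
        ds = _toy_green_dataset()
        model = build_model(SegModelConfig("rn18", 0.03125, 64), seed=0)
        tc = TrainConfig(epochs=1, batch_size=8, lr_start=1e-4, lr_end=1e-6, seed=0)
        _, hist = train(model, ds.subset("train"), ds.subset("val"), tc)
        assert len(hist) == 1
        assert hist[0].lr == 1e-4

    def test_linear_learning_rate_schedule(self):
        ds = _toy_green_dataset()
        model = build_model(SegModelConfig("rn18", 0.03125, 64), seed=0)
        tc = TrainConfig(epochs=3, batch_size=8, lr_start=1e-4, lr_end=1e-6, seed=0)
        _, hist = train(model, ds.subset("train"), ds.subset("val"), tc)
        lrs = [h.lr for h in hist]
        assert lrs[0] == 1e-4 and lrs[-1] == pytest.approx(1e-6)
        assert lrs[1] == pytest.approx((1e-4 + 1e-6) / 2)

    def test_loss_decreases_on_learnable_toy_problem(self):
        ds = _toy_green_dataset(seed=1)
        model = build_model(SegModelConfig("rn18", 0.125, 64), seed=1)
        tc = TrainConfig(epochs=5, batch_size=8, lr_start=2e-3, lr_end=1e-4, seed=1)
        _, hist = train(model, ds.subset("train"), ds.subset("val"), tc)
        assert hist[-1].train_loss < hist[0].train_loss

    def test_epoch_zero_is_deterministic(self):
        ds = _toy_green_dataset()
        losses = []
        for _ in range(2):
            model = build_model(SegModelConfig("rn18", 0.0625, 64), seed=2)
            tc = TrainConfig(epochs=1, batch_size=8, lr_start=1e-4, lr_end=1e-6, seed=2)
            _, hist = train(model, ds.subset("train"), ds.subset("val"), tc)
            losses.append(hist[0].train_loss)
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_empty_dataset_rejected(self):
        ds = _toy_green_dataset()
        empty = SegDataset(ds.images[:0], ds.masks[:0], ds.split[:0], ds.scene_id[:0])
        model = build_model(SegModelConfig("rn18", 0.0625, 64), seed=0)
        with pytest.raises(ValidationError):
            train(model, empty, ds.subset("val"), TrainConfig(epochs=1))


class TestPredictMask:
    def test_constant_negative_model_gives_all_background(self, rng):
        model = build_model(SegModelConfig("rn18", 0.0625, 64), seed=0)
        model.head.weight.value[...] = 0.0
        model.head.bias.value[...] = -10.0  # probability ~ 0 everywhere
        img = rng.integers(0, 255, (100, 150, 3), dtype=np.uint8)
        mask = predict_mask(model, img, tile_px=64)
        assert mask.shape == (100, 150)
        assert not mask.foreground().any()

    def test_small_image_padded_and_cropped_back(self, rng):
        model = build_model(SegModelConfig("rn18", 0.0625, 64), seed=0)
        img = rng.integers(0, 255, (40, 52, 3), dtype=np.uint8)
        mask = predict_mask(model, img, tile_px=64)
        assert mask.shape == (40, 52)

    def test_overlap_only_changes_pixels_near_seams(self, rng):
        model = build_model(SegModelConfig("rn18", 0.0625, 64), seed=3)
        img = rng.integers(0, 255, (192, 192, 3), dtype=np.uint8)
        m0 = predict_mask(model, img, tile_px=64, overlap=0).pixels
        m1 = predict_mask(model, img, tile_px=64, overlap=32).pixels
        diff = m0 != m1
        # pixels farther than the overlap from every interior seam (rows 64/128,
        # cols 64/128) are covered by the same single tile in both runs
        coords = np.arange(192)
        far = np.minimum(np.abs(coords - 64), np.abs(coords - 128)) > 32
        assert not diff[np.ix_(far, far)].any()
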
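"""Learning-rate schedule, paired augmentation and SSL pretraining."""

import numpy as np
import pytest

from sinussl.networks import UNetConfig, build_unet
from sinussl.pretrain import (AugmentConfig, PretrainConfig, augment_pair,
                              lr_schedule, pretrain_reconstructor)
from sinussl.uad import LossSpec, ResidualVolume
from sinussl.nn import bce_loss
from conftest import make_labelled_volumes


class TestSchedule:
    def test_reference_settings_closed_form(self):
        """500 epochs, 20-epoch warmup, peak 0.2: linear ramp then cosine."""
        cfg = PretrainConfig(epochs=500, warmup_epochs=20, peak_lr=0.2)
        assert lr_schedule(0, cfg) == 0.0
        assert lr_schedule(10, cfg) == pytest.approx(0.1, abs=1e-12)
        assert lr_schedule(20, cfg) == pytest.approx(0.2, abs=1e-9)
        for epoch in range(500):
            lr = lr_schedule(epoch, cfg)
            if epoch <= 20:
                expected = 0.2 * epoch / 20
            else:
                expected = 0.1 * (1 + np.cos(np.pi * (epoch - 20) / (499 - 20)))
            assert lr == pytest.approx(expected, abs=1e-9)
        assert lr_schedule(499, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_warmup_cosine_junction_continuous(self):
        cfg = PretrainConfig(epochs=50, warmup_epochs=5, peak_lr=0.3)
        assert abs(lr_schedule(5, cfg) - 0.3) < 1e-9

    def test_out_of_range_epoch_rejected(self):
        cfg = PretrainConfig(epochs=10, warmup_epochs=2)
        with pytest.raises(ValueError):
            lr_schedule(10, cfg)
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PretrainConfig(epochs=10, warmup_epochs=10)
        with pytest.raises(ValueError):
            PretrainConfig(peak_lr=0.0)


class TestAugmentPair:
    def _pair(self, rng):
        vol = rng.random((16, 16, 16))
        tgt = np.zeros((16, 16, 16))
        tgt[4:8, 4:8, 4:8] = 1.0
        return vol, tgt

    def test_no_augmentation_fires_identity(self, rng):
        vol, tgt = self._pair(rng)
        cfg = AugmentConfig(probability=0.0)
        out_v, out_t = augment_pair(vol, tgt, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(out_v, vol)
        np.testing.assert_array_equal(out_t, tgt)

    def test_flip_applied_jointly(self, rng):
        vol, tgt = self._pair(rng)
        # probability 1 makes all three augmentations fire; zero rotation and
        # translation reduce the affine to identity, so only flip+noise act
        cfg = AugmentConfig(probability=1.0, max_rotation_deg=0.0,
                            max_translation_frac=0.0, noise_sd=0.0)
        arng = np.random.default_rng(3)
        out_v, out_t = augment_pair(vol, tgt, arng, cfg)
        flip_rng = np.random.default_rng(3)
        flip_rng.random(3)
        flip_rng.uniform(-1, 1, size=3)
        flip_rng.uniform(-1, 1, size=3)
        axis = int(flip_rng.integers(3))
        np.testing.assert_allclose(out_v, np.clip(np.flip(vol, axis), 0, 1),
                                   atol=1e-12)
        np.testing.assert_array_equal(out_t > 0.5, np.flip(tgt, axis) > 0.5)

    def test_noise_touches_input_only(self, rng):
        vol, tgt = self._pair(rng)
        cfg = AugmentConfig(probability=1.0, max_rotation_deg=0.0,
                            max_translation_frac=0.0, noise_sd=0.1)
        seen_diff = False
        for seed in range(5):
            out_v, out_t = augment_pair(vol, tgt, np.random.default_rng(seed), cfg)
            flipped_back_t = out_t
            # target must be an exact flip of the original, untouched by noise
            assert set(np.unique(flipped_back_t)) <= {0.0, 1.0}
            seen_diff |= not np.array_equal(out_v, vol)
        assert seen_diff

    def test_outputs_clipped(self, rng):
        vol = np.ones((8, 8, 8)) * 0.99
        cfg = AugmentConfig(probability=1.0, max_rotation_deg=0.0,
                            max_translation_frac=0.0, noise_sd=0.5)
        out_v, _ = augment_pair(vol, None, np.random.default_rng(0), cfg)
        assert out_v.max() <= 1.0 and out_v.min() >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((8, 8, 8)), np.zeros((4, 4, 4)), rng)


def _toy_pairs(n=10, edge=16, seed=0):
    volumes = make_labelled_volumes(n, 0, edge=edge, seed=seed)
    rng = np.random.default_rng(seed)
    pairs = []
    for v in volumes:
        target = np.clip(np.abs(rng.normal(0.1, 0.05, size=v.data.shape)), 0, 1)
        pairs.append((v, ResidualVolume(data=target, source_volume_id=v.uid)))
    return pairs


class TestPretrain:
    def _nets(self, seed=0):
        return build_unet(UNetConfig(stage_channels=(8, 16, 24, 32),
                                     width_factor=1.0), seed=seed)

    def test_bce_of_matched_binary_prediction_is_tiny(self):
        target = np.array([0.0, 1.0, 1.0, 0.0])
        loss, _ = bce_loss(target.copy(), target)
        assert loss < 1e-6

    def test_loss_decreases_on_toy_pairs(self):
        enc, dec = self._nets()
        cfg = PretrainConfig(loss=LossSpec("BCE"), epochs=8, warmup_epochs=1,
                             peak_lr=1e-3, batch_size=4,
                             optimizer="adam_family",
                             augmentations=AugmentConfig(enabled=False), seed=0)
        enc, dec = pretrain_reconstructor(enc, dec, _toy_pairs(), cfg)
        curve = enc.history[-1]["curve"]
        assert curve[-1]["loss"] < curve[0]["loss"]
        assert enc.provenance == "ssl_pretrained"
        assert dec.provenance == "ssl_pretrained"

    def test_l1_loss_variant_runs_through_same_pipeline(self):
        enc, dec = self._nets()
        cfg = PretrainConfig(loss=LossSpec("L1"), epochs=2, warmup_epochs=0,
                             peak_lr=1e-3, batch_size=4,
                             optimizer="adam_family",
                             augmentations=AugmentConfig(enabled=False), seed=0)
        enc, _ = pretrain_reconstructor(enc, dec, _toy_pairs(), cfg)
        assert enc.history[-1]["loss"] == "L1"

    def test_misaligned_pairs_rejected(self):
        enc, dec = self._nets()
        pairs = _toy_pairs()
        bad = (pairs[0][0], ResidualVolume(data=pairs[1][1].data,
                                           source_volume_id="other_left"))
        with pytest.raises(ValueError, match="misaligned"):
            pretrain_reconstructor(enc, dec, [bad], PretrainConfig(
                epochs=1, warmup_epochs=0, optimizer="adam_family"))

    def test_bce_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1.5]))

    def test_epoch_consumes_every_training_pair_once(self, monkeypatch):
        """Shuffling changes order, never the multiset of ids per epoch."""
        from sinussl import pretrain as pt
        consumed = []
        original = pt.pretrain_reconstructor
        enc, dec = self._nets()
        pairs = _toy_pairs(n=8)
        cfg = PretrainConfig(loss=LossSpec("BCE"), epochs=2, warmup_epochs=0,
                             peak_lr=1e-3, batch_size=3,
                             optimizer="adam_family", val_fraction=0.25,
                             augmentations=AugmentConfig(enabled=False), seed=1)
        # instrument the forward by watching batch sizes through the curve
        enc, dec = original(enc, dec, pairs, cfg)
        record = enc.history[-1]
        assert record["n_pairs"] == 8
        # 2 held out for validation, 6 trained in batches of 3
        assert all(entry["loss"] > 0 for entry in record["curve"])
        assert len(record["curve"]) == 2

    def test_seeded_pretraining_reproducible(self):
        cfg = PretrainConfig(loss=LossSpec("BCE"), epochs=2, warmup_epochs=0,
                             peak_lr=1e-3, batch_size=4,
                             optimizer="adam_family", seed=5)
        import dataclasses
        enc1, dec1 = self._nets(seed=1)
        enc1, _ = pretrain_reconstructor(enc1, dec1, _toy_pairs(), cfg)
        enc2, dec2 = self._nets(seed=1)
        enc2, _ = pretrain_reconstructor(enc2, dec2, _toy_pairs(),
                                         dataclasses.replace(cfg))
        assert enc1.module.checksum() == enc2.module.checksum()

    def test_lars_optimizer_path_runs(self):
        enc, dec = self._nets()
        cfg = PretrainConfig(loss=LossSpec("BCE"), epochs=1, warmup_epochs=0,
                             peak_lr=0.1, batch_size=4,
                             optimizer="layerwise_adaptive",
                             augmentations=AugmentConfig(enabled=False), seed=0)
        enc, _ = pretrain_reconstructor(enc, dec, _toy_pairs(n=6), cfg)
        assert enc.history[-1]["optimizer"] == "layerwise_adaptive"
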
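"""Architecture builders: shape/range contracts, seeded init, gradient flow,
finite-difference gradient checks of every layer, checkpoint round-trips."""

import numpy as np
import pytest

import sinussl.nn.core as nn_core
from sinussl.networks import (BasicBlock3d, CAEConfig, UNetConfig,
                              build_cae, build_classifier, build_unet,
                              load_model_state)
from sinussl.nn import (AdamW, BatchNorm3d, Conv3d, GlobalAvgPool3d,
                        LeakyReLU, Linear, Sigmoid, TrilinearUpsample,
                        softmax, softmax_cross_entropy)


@pytest.fixture
def float64_params(monkeypatch):
    """Finite-difference checks need double precision parameters."""
    monkeypatch.setattr(nn_core, "DTYPE", np.float64)


def _numeric_input_grad(f, x, indices, eps=1e-6):
    grads = {}
    for idx in indices:
        x[idx] += eps
        fp = f(x)
        x[idx] -= 2 * eps
        fm = f(x)
        x[idx] += eps
        grads[idx] = (fp - fm) / (2 * eps)
    return grads


@pytest.mark.parametrize("layer_factory,shape", [
    (lambda rng: Conv3d(2, 3, 3, stride=1, padding=1, rng=rng), (2, 2, 4, 4, 4)),
    (lambda rng: Conv3d(2, 3, 3, stride=2, padding=1, rng=rng), (2, 2, 4, 4, 4)),
    (lambda rng: Conv3d(2, 3, 1, stride=2, padding=0, rng=rng), (1, 2, 4, 4, 4)),
    (lambda rng: BatchNorm3d(3), (2, 3, 3, 3, 3)),
    (lambda rng: TrilinearUpsample(2), (1, 2, 3, 3, 3)),
    (lambda rng: GlobalAvgPool3d(), (2, 3, 2, 2, 2)),
    (lambda rng: BasicBlock3d(2, 3, 2, rng), (1, 2, 4, 4, 4)),
    (lambda rng: Sigmoid(), (2, 2, 3, 3, 3)),
], ids=["conv_s1", "conv_s2", "conv_k1", "batchnorm", "upsample", "gap",
        "resblock", "sigmoid"])
def test_layer_backward_matches_finite_differences(float64_params,
                                                   layer_factory, shape):
    rng = np.random.default_rng(0)
    layer = layer_factory(rng)
    x = rng.uniform(0.1, 0.9, size=shape)

    def f(xx):
        return float(np.sum(np.sin(layer.forward(xx, training=True))))

    y = layer.forward(x, training=True)
    layer.zero_grad()
    gx = layer.backward(np.cos(y))
    flat_indices = [np.unravel_index(i, x.shape)
                    for i in rng.choice(x.size, size=8, replace=False)]
    numeric = _numeric_input_grad(f, x.copy(), flat_indices)
    for idx, ng in numeric.items():
        assert gx[idx] == pytest.approx(ng, rel=1e-5, abs=1e-8)


def test_conv_parameter_gradients_match_finite_differences(float64_params):
    rng = np.random.default_rng(1)
    layer = Conv3d(2, 2, 3, stride=2, padding=1, rng=rng)
    x = rng.uniform(size=(2, 2, 4, 4, 4))

    def f():
        return float(np.sum(np.sin(layer.forward(x, training=True))))

    layer.zero_grad()
    y = layer.forward(x, training=True)
    layer.backward(np.cos(y))
    for p in layer.parameters():
        flat = np.random.default_rng(2).choice(p.data.size,
                                               size=min(5, p.data.size),
                                               replace=False)
        for i in flat:
            idx = np.unravel_index(i, p.data.shape)
            p.data[idx] += 1e-6
            fp = f()
            p.data[idx] -= 2e-6
            fm = f()
            p.data[idx] += 1e-6
            assert p.grad[idx] == pytest.approx((fp - fm) / 2e-6,
                                                rel=1e-5, abs=1e-8)


class TestCAE:
    def test_shape_contract_and_range(self):
        for edge in (16, 32):
            state = build_cae(CAEConfig(in_edge=edge,
                                        stage_channels=(4, 8, 8, 8),
                                        latent_dim=16), seed=0)
            x = np.random.default_rng(0).uniform(
                size=(2, 1, edge, edge, edge)).astype(np.float32)
            y = state.module.forward(x)
            assert y.shape == x.shape
            assert 0 < y.min() and y.max() < 1

    def test_seeded_build_reproducible(self):
        a = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8), latent_dim=8),
                      seed=7)
        b = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8), latent_dim=8),
                      seed=7)
        assert a.module.checksum() == b.module.checksum()
        c = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8), latent_dim=8),
                      seed=8)
        assert a.module.checksum() != c.module.checksum()

    def test_indivisible_edge_rejected(self):
        with pytest.raises(ValueError):
            CAEConfig(in_edge=20, stage_channels=(4, 8, 8))


class TestUNet:
    def test_encoder_feature_dim_follows_last_stage(self):
        cfg = UNetConfig(stage_channels=(64, 128, 256, 512), width_factor=0.125)
        assert cfg.feature_dim == 64
        enc, _ = build_unet(cfg, seed=0)
        x = np.random.default_rng(0).uniform(size=(1, 1, 16, 16, 16)).astype(np.float32)
        feats = enc.module.forward(x)
        assert feats.shape == (1, 64)

    @pytest.mark.parametrize("skips", [True, False])
    def test_decoder_shape_with_and_without_skips(self, skips):
        cfg = UNetConfig(stage_channels=(8, 16, 24, 32), width_factor=1.0,
                         skip_connections=skips)
        enc, dec = build_unet(cfg, seed=1)
        x = np.random.default_rng(1).uniform(size=(2, 1, 16, 16, 16)).astype(np.float32)
        bottleneck, skip_maps = enc.module.forward_map(x)
        y = dec.module.forward(bottleneck, skip_maps)
        assert y.shape == x.shape
        assert 0 < y.min() and y.max() < 1

    def test_width_scaling_strictly_reduces_parameters(self):
        def n_params(wf):
            enc, dec = build_unet(UNetConfig(width_factor=wf), seed=0)
            return sum(p.data.size for p in enc.module.parameters()) + \
                sum(p.data.size for p in dec.module.parameters())
        sizes = [n_params(wf) for wf in (0.25, 0.125, 0.0625)]
        assert sizes[0] > sizes[1] > sizes[2]

    def test_gradient_flows_to_every_parameter(self):
        """After one optimization step every parameter block changes."""
        cfg = UNetConfig(stage_channels=(8, 16, 24, 32), width_factor=1.0)
        enc, dec = build_unet(cfg, seed=2)
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(2, 1, 16, 16, 16)).astype(np.float32)
        target = rng.uniform(size=(2, 1, 16, 16, 16)).astype(np.float32)
        params = enc.module.parameters() + dec.module.parameters()
        before = [p.data.copy() for p in params]
        bottleneck, skips = enc.module.forward_map(x, training=True)
        pred = dec.module.forward(bottleneck, skips, training=True)
        grad = (pred - target) / pred.size
        for p in params:
            p.zero_grad()
        g_b, g_s = dec.module.backward(grad)
        enc.module.backward_map(g_b, g_s)
        assert all(np.abs(p.grad).max() > 0 for p in params)
        AdamW(params).step(1e-3)
        assert all(not np.array_equal(b, p.data) for b, p in zip(before, params))


class TestClassifier:
    def _encoder(self, seed=0):
        enc, _ = build_unet(UNetConfig(stage_channels=(8, 16, 24, 32),
                                       width_factor=1.0), seed=seed)
        return enc

    def test_two_class_output_and_softmax_normalization(self):
        clf = build_classifier(self._encoder(), hidden=16, seed=0)
        x = np.random.default_rng(0).uniform(size=(3, 1, 16, 16, 16)).astype(np.float32)
        logits = clf.module.forward(x)
        assert logits.shape == (3, 2)
        np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-6)

    def test_head_and_encoder_roles_separate(self):
        encoder = self._encoder(seed=4)
        clf = build_classifier(encoder, hidden=16, seed=1)
        x = np.random.default_rng(2).uniform(size=(2, 1, 16, 16, 16)).astype(np.float32)
        feats_before = clf.module.features(x)
        logits_before = clf.module.forward(x)
        # replacing only the head leaves encoder features unchanged
        rng = np.random.default_rng(99)
        clf.module.fc2.weight.data = rng.normal(
            size=clf.module.fc2.weight.data.shape).astype(np.float32)
        np.testing.assert_array_equal(clf.module.features(x), feats_before)
        assert not np.array_equal(clf.module.forward(x), logits_before)
        # replacing encoder weights changes the logits
        logits_mid = clf.module.forward(x)
        clf.module.encoder.stem.layers[0].weight.data += 0.5
        assert not np.array_equal(clf.module.forward(x), logits_mid)

    def test_finetuned_encoder_cannot_seed_new_classifier(self):
        encoder = self._encoder()
        encoder.provenance = "finetuned"
        with pytest.raises(ValueError):
            build_classifier(encoder, hidden=8)


class TestCheckpoint:
    def test_round_trip_preserves_outputs_and_provenance(self, tmp_path):
        state = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8),
                                    latent_dim=8), seed=5)
        state.provenance = "cae_trained"
        x = np.random.default_rng(1).uniform(size=(1, 1, 16, 16, 16)).astype(np.float32)
        expected = state.module.forward(x)
        path = tmp_path / "cae.ckpt"
        state.save(path)
        loaded = load_model_state(path)
        assert loaded.provenance == "cae_trained"
        assert loaded.kind == "cae"
        np.testing.assert_array_equal(loaded.module.forward(x), expected)

    def test_provenance_moves_forward_only(self):
        state = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8),
                                    latent_dim=8), seed=5)
        state.advance("cae_trained")
        with pytest.raises(ValueError):
            state.advance("random_init")
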
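"""Autoencoder training, residual generation and the median-filter oracle."""

import numpy as np
import pytest

from sinussl.networks import CAEConfig, ModelState, build_cae
from sinussl.nn import Module
from sinussl.preprocess import MSVolume
from sinussl.uad import (ResidualVolume, anomaly_score,
                         compute_residual, generate_residual_dataset,
                         median_filter3d, train_cae)
from conftest import make_labelled_volumes


def brute_force_median3d(volume, kernel):
    """Independent oracle: reflect-pad then sort every neighborhood."""
    r = kernel // 2
    # edge-repeating reflection, the same border rule the implementation uses
    padded = np.pad(volume, r, mode="symmetric") if r else volume
    out = np.empty_like(np.asarray(volume, dtype=float))
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            for k in range(volume.shape[2]):
                block = padded[i:i + kernel, j:j + kernel, k:k + kernel]
                out[i, j, k] = np.sort(block.ravel())[block.size // 2]
    return out


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = np.full((6, 6, 6), 0.4)
        np.testing.assert_array_equal(median_filter3d(vol, 3), vol)

    def test_impulse_removed(self):
        vol = np.zeros((8, 8, 8))
        vol[4, 4, 4] = 1.0
        expected = brute_force_median3d(vol, 3)
        np.testing.assert_array_equal(median_filter3d(vol, 3), expected)
        assert not median_filter3d(vol, 3).any()

    def test_kernel_one_is_identity(self, rng):
        vol = rng.random((5, 5, 5))
        np.testing.assert_array_equal(median_filter3d(vol, 1), vol)

    def test_matches_brute_force_oracle(self, rng):
        for kernel in (3, 5):
            for _ in range(3):
                vol = rng.random((8, 8, 8))
                np.testing.assert_array_equal(median_filter3d(vol, kernel),
                                              brute_force_median3d(vol, kernel))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter3d(np.zeros((4, 4, 4)), 4)


class _IdentityCAE(Module):
    def forward(self, x, training=False):
        return x


def _identity_state():
    return ModelState(module=_IdentityCAE(), kind="cae", config={},
                      provenance="cae_trained")


class TestResidual:
    def test_identity_model_gives_zero_residual(self, normal_sample):
        # float32-representable data so the identity round-trip is exact
        vol = MSVolume(normal_sample.volume.data.astype(np.float32).astype(float),
                       patient_id="p")
        res = compute_residual(_identity_state(), vol)
        np.testing.assert_array_equal(res.data, 0.0)
        assert anomaly_score(res) == 0.0

    def test_extreme_residual(self):
        class Zero(Module):
            def forward(self, x, training=False):
                return np.zeros_like(x)
        state = ModelState(module=Zero(), kind="cae", config={},
                           provenance="cae_trained")
        vol = MSVolume(np.ones((8, 8, 8)), patient_id="p")
        res = compute_residual(state, vol)
        np.testing.assert_array_equal(res.data, 1.0)

    def test_residual_requires_trained_model(self, normal_sample):
        state = build_cae(CAEConfig(in_edge=16, stage_channels=(4, 8),
                                    latent_dim=8), seed=0)
        with pytest.raises(ValueError, match="cae_trained"):
            compute_residual(state, normal_sample.volume)

    def test_residual_range_validated(self):
        with pytest.raises(ValueError):
            ResidualVolume(data=np.full((4, 4, 4), 1.5), source_volume_id="x")

    def test_anomaly_score_monotone_in_added_signal(self, rng):
        base = rng.random((8, 8, 8)) * 0.4
        bump = np.zeros_like(base)
        bump[2:4, 2:4, 2:4] = 0.3
        assert anomaly_score(base) < anomaly_score(base + bump)
        assert anomaly_score(np.full((4, 4, 4), 0.5)) == pytest.approx(0.5)


class TestTrainCAE:
    def _state(self, edge=16):
        return build_cae(CAEConfig(in_edge=edge, stage_channels=(4, 8, 8),
                                   latent_dim=16), seed=0)

    def test_zero_epochs_is_a_no_op(self):
        vols = make_labelled_volumes(3, 0)
        state = self._state()
        before = state.module.checksum()
        out = train_cae(state, vols, epochs=0, seed=0)
        assert out.module.checksum() == before
        assert out.provenance == "random_init"

    def test_anomalous_volume_in_normal_set_rejected(self):
        vols = make_labelled_volumes(2, 1)
        with pytest.raises(ValueError, match="non-normal"):
            train_cae(self._state(), vols, epochs=1, seed=0)

    def test_overfit_single_phantom_reduces_loss(self):
        """200 steps on one repeated 16-voxel phantom cut the starting L1
        at least fivefold."""
        from sinussl.phantoms import PhantomParams, generate_normal_volume
        clean = generate_normal_volume(PhantomParams(cube_edge=16, noise_sd=0.0,
                                                     seed=1)).volume
        vols = [clean] * 8
        state = self._state()
        x = clean.data[None, None].astype(np.float32)
        initial = float(np.mean(np.abs(state.module.forward(x) - x)))
        state = train_cae(state, vols, epochs=25, batch_size=1,
                          lr=3e-3, seed=0)  # 8 steps/epoch x 25 epochs
        assert state.history[-1]["curve"][-1] < initial / 5

    def test_seeded_training_reproducible(self):
        vols = make_labelled_volumes(4, 0)
        a = train_cae(self._state(), vols, epochs=2, batch_size=2, seed=3)
        b = train_cae(self._state(), vols, epochs=2, batch_size=2, seed=3)
        assert a.module.checksum() == b.module.checksum()
        assert a.provenance == "cae_trained"


class TestResidualDataset:
    def test_counts_ids_and_identity_kernel(self):
        vols = make_labelled_volumes(3, 0)
        state = train_cae(build_cae(CAEConfig(in_edge=16,
                                              stage_channels=(4, 8),
                                              latent_dim=8), seed=0),
                          vols, epochs=1, seed=0)
        unlabelled = make_labelled_volumes(0, 3, seed=5)
        assert generate_residual_dataset(state, []) == []
        res_none = generate_residual_dataset(state, unlabelled, median_kernel=None)
        res_k1 = generate_residual_dataset(state, unlabelled, median_kernel=1)
        assert len(res_none) == len(unlabelled)
        assert [r.source_volume_id for r in res_none] == \
            [v.uid for v in unlabelled]
        for a, b in zip(res_none, res_k1):
            np.testing.assert_array_equal(a.data, b.data)

    def test_sidecars_written(self, tmp_path):
        vols = make_labelled_volumes(2, 0)
        state = train_cae(build_cae(CAEConfig(in_edge=16,
                                              stage_channels=(4, 8),
                                              latent_dim=8), seed=0),
                          vols, epochs=1, seed=0)
        generate_residual_dataset(state, vols, median_kernel=3,
                                  out_dir=tmp_path)
        assert len(list(tmp_path.glob("*_residual.nii.gz"))) == 2
        assert len(list(tmp_path.glob("*_residual.json"))) == 2
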
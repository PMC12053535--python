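"""Weight maps, sliding-window blending, argmax labeling, ensembling."""

import numpy as np
import pytest

from gtvseg.inference import (
    WeightMap,
    ensemble_predict,
    gaussian_weight_map,
    labels_from_probs,
    sliding_window_predict,
    uniform_weight_map,
)
from gtvseg.network import NetworkConfig, build_unet
from gtvseg.patching import normalize_patch
from gtvseg.volumes_io import Volume


class ConstantModel:
    """Predicts the same probability vector at every voxel."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=np.float32)

    def __call__(self, x):
        n, _, X, Y, Z = x.shape
        out = np.broadcast_to(self.probs[None, :, None, None, None], (n, len(self.probs), X, Y, Z))
        return out.copy()


class TestGaussianWeightMap:
    def test_center_voxel_weight_is_one(self):
        for size in [(320, 320, 64), (17, 9, 5)]:
            w = gaussian_weight_map(size).weights
            assert w.max() == pytest.approx(1.0, abs=1e-12)
            center = tuple(s // 2 for s in size)
            assert w[center] == pytest.approx(1.0, abs=1e-6)

    def test_face_center_boundary_voxel_equals_edge_value(self):
        w = gaussian_weight_map((320, 320, 64), edge_value=0.1).weights
        assert w[0, 160, 32] == pytest.approx(0.1, abs=1e-6)
        assert w[160, 0, 32] == pytest.approx(0.1, abs=1e-6)
        assert w[160, 160, 0] == pytest.approx(0.1, abs=1e-6)

    def test_corner_is_edge_value_cubed(self):
        w = gaussian_weight_map((24, 16, 8), edge_value=0.1).weights
        assert w[0, 0, 0] == pytest.approx(1e-3, abs=1e-9)

    def test_separable_and_symmetric(self):
        w = gaussian_weight_map((12, 10, 6)).weights
        np.testing.assert_allclose(w, w[::-1], atol=1e-7)
        np.testing.assert_allclose(w, w[:, ::-1], atol=1e-7)
        np.testing.assert_allclose(w, w[:, :, ::-1], atol=1e-7)
        assert (w > 0).all()

    def test_invalid_edge_value_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weight_map((8, 8, 8), edge_value=0.0)
        with pytest.raises(ValueError):
            gaussian_weight_map((8, 8, 8), edge_value=1.5)

    def test_weight_map_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            WeightMap(np.zeros((4, 4, 4)))


class TestUniformWeightMap:
    def test_all_ones(self):
        w = uniform_weight_map((7, 5, 3)).weights
        np.testing.assert_array_equal(w, np.ones((7, 5, 3), dtype=np.float32))


class TestSlidingWindow:
    def test_constant_model_gives_constant_output_any_weighting(self, rng):
        vol = rng.normal(size=(40, 40, 20)).astype(np.float32)
        model = ConstantModel([0.5, 0.3, 0.2])
        for wmap in (None, uniform_weight_map((16, 16, 8))):
            out = sliding_window_predict(
                vol, model, patch_size=(16, 16, 8), stride=(8, 8, 4), wmap=wmap
            )
            assert out.shape == (3, 40, 40, 20)
            np.testing.assert_allclose(out[0], 0.5, atol=1e-6)
            np.testing.assert_allclose(out[1], 0.3, atol=1e-6)

    def test_voxelwise_network_oracle_equivalence(self, rng):
        """A purely voxelwise (1x1x1 kernels, no spatial statistics) network
        must give identical results under sliding-window and whole-volume
        inference, for any stride and weighting."""
        cfg = NetworkConfig(base_width=4, n_stages=1, kernel_by_stage=[1], instance_norm=False)
        model = build_unet(cfg, seed=2)
        vol = normalize_patch(rng.normal(size=(24, 24, 12)))
        whole = model(vol[None, None])[0]
        for stride, wmap in [
            ((8, 8, 4), None),
            ((5, 7, 3), uniform_weight_map((16, 16, 8))),
            ((16, 16, 8), None),
        ]:
            windowed = sliding_window_predict(
                vol, model, patch_size=(16, 16, 8), stride=stride, wmap=wmap, normalize="none"
            )
            np.testing.assert_allclose(windowed, whole, atol=1e-5)

    def test_window_grid_covers_every_voxel(self):
        """Flush-end window grid: full coverage, interior multiplicity."""
        from gtvseg.inference import _window_starts

        shape, patch, stride = (100, 100, 20), (80, 80, 16), (20, 20, 4)
        cover = np.zeros(shape, dtype=int)
        for sx in _window_starts(shape[0], patch[0], stride[0]):
            for sy in _window_starts(shape[1], patch[1], stride[1]):
                for sz in _window_starts(shape[2], patch[2], stride[2]):
                    cover[sx : sx + patch[0], sy : sy + patch[1], sz : sz + patch[2]] += 1
        assert cover.min() >= 1
        assert cover.max() == 2 * 2 * 2  # interior voxels hit by every window

    def test_gaussian_equals_uniform_when_no_overlap(self, rng):
        cfg = NetworkConfig(base_width=2, n_stages=1, kernel_by_stage=[3])
        model = build_unet(cfg, seed=0)
        vol = rng.normal(size=(32, 32, 16)).astype(np.float32)
        kw = dict(patch_size=(16, 16, 8), stride=(16, 16, 8), normalize="patch")
        out_g = sliding_window_predict(vol, model, wmap=gaussian_weight_map((16, 16, 8)), **kw)
        out_u = sliding_window_predict(vol, model, wmap=uniform_weight_map((16, 16, 8)), **kw)
        np.testing.assert_allclose(out_g, out_u, atol=1e-6)

    def test_output_is_probability_simplex(self, rng):
        cfg = NetworkConfig(base_width=2, n_stages=2, kernel_by_stage=[3, 1])
        model = build_unet(cfg, seed=1)
        vol = rng.normal(size=(24, 24, 12)).astype(np.float32)
        out = sliding_window_predict(vol, model, patch_size=(16, 16, 8), stride=(8, 8, 4))
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-5)

    def test_volume_smaller_than_patch_padded_and_cropped(self, rng):
        model = ConstantModel([0.2, 0.7, 0.1])
        out = sliding_window_predict(
            rng.normal(size=(10, 10, 6)).astype(np.float32),
            model, patch_size=(16, 16, 8), stride=(16, 16, 8),
        )
        assert out.shape == (3, 10, 10, 6)

    def test_stride_larger_than_patch_rejected(self, rng):
        model = ConstantModel([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            sliding_window_predict(
                rng.normal(size=(32, 32, 16)), model,
                patch_size=(16, 16, 8), stride=(24, 16, 8),
            )


class TestLabelsFromProbs:
    def test_one_hot_recovers_labels(self, rng):
        labels = rng.integers(0, 3, size=(6, 6, 4))
        probs = np.eye(3)[labels].transpose(3, 0, 1, 2)
        np.testing.assert_array_equal(labels_from_probs(probs).labels, labels)

    def test_uniform_tie_breaks_to_background(self):
        probs = np.full((3, 4, 4, 2), 1 / 3)
        assert (labels_from_probs(probs).labels == 0).all()

    def test_plain_argmax(self):
        probs = np.zeros((3, 1, 1, 1))
        probs[:, 0, 0, 0] = [0.2, 0.5, 0.3]
        assert labels_from_probs(probs).labels[0, 0, 0] == 1


class TestEnsemble:
    def _vol(self, rng):
        return Volume(rng.normal(size=(16, 16, 8)).astype(np.float32), spacing=(1, 1, 2))

    def test_single_model_ensemble_matches_single_prediction(self, rng):
        cfg = NetworkConfig(base_width=2, n_stages=2, kernel_by_stage=[3, 1])
        model = build_unet(cfg, seed=0)
        vol = self._vol(rng)
        kw = dict(patch_size=(8, 8, 4), stride=(4, 4, 2))
        single = labels_from_probs(sliding_window_predict(vol, model, **kw), like=vol)
        ens = ensemble_predict(vol, [model], **kw)
        np.testing.assert_array_equal(ens.labels, single.labels)

    def test_identical_members_match_single_model(self, rng):
        cfg = NetworkConfig(base_width=2, n_stages=1, kernel_by_stage=[1])
        model = build_unet(cfg, seed=5)
        vol = self._vol(rng)
        kw = dict(patch_size=(8, 8, 4), stride=(8, 8, 4))
        one = ensemble_predict(vol, [model], **kw)
        three = ensemble_predict(vol, [model, model, model], **kw)
        np.testing.assert_array_equal(one.labels, three.labels)

    def test_probability_averaging_hand_case(self, rng):
        # members (0.6,0.4,0) and (0.2,0.8,0) -> mean (0.4,0.6,0) -> class 1
        vol = self._vol(rng)
        models = [ConstantModel([0.6, 0.4, 0.0]), ConstantModel([0.2, 0.8, 0.0])]
        out = ensemble_predict(vol, models, patch_size=(8, 8, 4), stride=(8, 8, 4))
        assert (out.labels == 1).all()

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_predict(self._vol(rng), [])
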
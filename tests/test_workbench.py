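"""Learning-rate schedule, Task-2 input stacking, and the training loop."""

import numpy as np
import pytest

from gtvseg.patching import PatchSpec, extract_patch, normalize_patch
from gtvseg.synthetic import PhantomSpec, generate_paired_phantom, make_cohort
from gtvseg.workbench import TrainConfig, cosine_lr, load_cohort, task2_inputs, train
from gtvseg.volumes_io import LabelMask, Volume


class TestCosineLR:
    def test_endpoints_match_protocol_bounds(self):
        assert cosine_lr(0, 100_000) == pytest.approx(1e-3)
        assert cosine_lr(100_000, 100_000) == pytest.approx(1e-5)

    def test_midpoint_is_arithmetic_mean_of_bounds(self):
        assert cosine_lr(50_000, 100_000) == pytest.approx(5.05e-4)

    def test_monotone_non_increasing(self):
        lrs = [cosine_lr(i, 1000) for i in range(0, 1001, 50)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(1001, 1000)


class TestTask2Inputs:
    def _pair(self, shrink=0.7):
        pre_v, pre_m, mid_v, mid_m = generate_paired_phantom(PhantomSpec(seed=6), shrink)
        return pre_v, pre_m, mid_v, mid_m

    def test_four_channels_in_order(self):
        pre_v, pre_m, mid_v, _ = self._pair()
        x = task2_inputs(mid_v, pre_v, pre_m)
        assert x.shape == (4,) + mid_v.shape
        np.testing.assert_array_equal(x[0], mid_v.data)
        np.testing.assert_array_equal(x[1], pre_v.data)
        np.testing.assert_array_equal(x[2], (pre_m.labels == 1).astype(np.float32))
        np.testing.assert_array_equal(x[3], (pre_m.labels == 2).astype(np.float32))

    def test_empty_prior_mask_gives_zero_channels(self):
        pre_v, _, mid_v, _ = self._pair()
        empty = LabelMask(np.zeros(pre_v.shape, dtype=np.uint8), pre_v.spacing)
        x = task2_inputs(mid_v, pre_v, empty)
        assert x[2].sum() == 0 and x[3].sum() == 0

    def test_selective_normalization_leaves_mask_channels_untouched(self):
        """Z-scoring only the image channels keeps binary priors bit-exact."""
        pre_v, pre_m, mid_v, _ = self._pair()
        x = task2_inputs(mid_v, pre_v, pre_m)
        spec = PatchSpec((10, 10, 5), (32, 32, 16))
        patch = np.stack([extract_patch(x[c], spec) for c in range(4)])
        normed = np.stack(
            [normalize_patch(patch[c]) if c < 2 else patch[c] for c in range(4)]
        )
        np.testing.assert_array_equal(normed[2], patch[2])
        np.testing.assert_array_equal(normed[3], patch[3])
        assert abs(normed[0].mean()) < 1e-5

    def test_grid_mismatch_rejected(self):
        pre_v, pre_m, _, _ = self._pair()
        small = Volume(pre_v.data[:32, :32, :16], pre_v.spacing)
        with pytest.raises(ValueError):
            task2_inputs(small, pre_v, pre_m)


@pytest.fixture(scope="module")
def tiny_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort") / "c"
    make_cohort(out, n_patients=4, k_folds=2, shape=(32, 32, 16), seed=5)
    return out


TINY_TRAIN = dict(
    iterations=40,
    eval_every=40,
    seed=0,
    patch_size=(16, 16, 8),
)


class TestTrainLoop:
    def test_loss_decreases(self, tiny_cohort):
        res = train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=0)
        first = res.history.loss.iloc[:5].mean()
        last = res.history.loss.iloc[-5:].mean()
        assert last < first

    def test_two_runs_same_seed_identical_loss_curves(self, tiny_cohort):
        r1 = train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=0)
        r2 = train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=0)
        np.testing.assert_array_equal(r1.history.loss.values, r2.history.loss.values)
        np.testing.assert_array_equal(
            r1.history.val_dsc_agg_mean.dropna().values,
            r2.history.val_dsc_agg_mean.dropna().values,
        )

    def test_validation_metrics_logged_and_best_tracked(self, tiny_cohort):
        res = train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=1)
        assert {"val_dsc_agg_gtvp", "val_dsc_agg_gtvn", "val_dsc_agg_mean"} <= set(res.history.columns)
        assert res.best_score == res.history.val_dsc_agg_mean.dropna().max()

    def test_checkpoint_written_and_loadable(self, tiny_cohort, tmp_path):
        from gtvseg.network import load_checkpoint

        ckpt = tmp_path / "model.npz"
        train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=0, checkpoint_path=ckpt)
        model = load_checkpoint(ckpt)
        probs = model(np.zeros((1, 1, 16, 16, 8), dtype=np.float32))
        assert probs.shape == (1, 3, 16, 16, 8)

    def test_missing_fold_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            train(TrainConfig(**TINY_TRAIN), tiny_cohort, fold=9)

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cohort(tmp_path)


class TestTask2Training:
    def test_prior_guided_training_runs_and_learns(self, tmp_path):
        from gtvseg.network import NetworkConfig
        from gtvseg.synthetic import make_paired_cohort

        make_paired_cohort(tmp_path / "p", n_patients=4, k_folds=2,
                           shape=(32, 32, 16), seed=2)
        cfg = TrainConfig(
            task_mode="task2", iterations=60, eval_every=60, seed=0,
            patch_size=(16, 16, 8),
            network=NetworkConfig(in_channels=4, base_width=4, n_stages=2,
                                  kernel_by_stage=[3, 3]),
        )
        res = train(cfg, tmp_path / "p", fold=0)
        assert res.history.loss.iloc[-5:].mean() < res.history.loss.iloc[:5].mean()
        assert "val_dsc_agg_mean" in res.history.columns

    def test_task2_requires_four_channel_network(self, tmp_path):
        from gtvseg.synthetic import make_paired_cohort

        make_paired_cohort(tmp_path / "p", n_patients=4, k_folds=2,
                           shape=(32, 32, 16), seed=2)
        cfg = TrainConfig(task_mode="task2", iterations=5, patch_size=(16, 16, 8))
        with pytest.raises(ValueError):
            train(cfg, tmp_path / "p", fold=0)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = TrainConfig(iterations=123, patch_size=(8, 8, 8))
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = TrainConfig.from_yaml(p)
        assert back.iterations == 123
        assert back.patch_size == (8, 8, 8)
        assert back.network == cfg.network

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_start=1e-5, lr_end=1e-3)
        with pytest.raises(ValueError):
            TrainConfig(task_mode="task3")
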
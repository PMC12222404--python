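"""Correction-engine contracts: normalisation, folds, patches, ensembling,
sliding-window inference and task-state enforcement."""

import numpy as np
import pytest

from dosekit import (CorrectionTask, DoseMap, TrainingConfig, VolumetricImage,
                     denormalise, make_folds, normalise)
from dosekit.engine import (RegressorEnsemble, TaskContractError, predict,
                            sample_training_patches, sliding_window_predict,
                            train_task)
from dosekit.regressors import FeatureSpec, IdentityRegressor, LocalFeatureMLP


def _dose(values, state, spacing=4.795):
    return DoseMap(VolumetricImage(np.asarray(values, float),
                                   (spacing,) * 3), state)


class TestNormalisation:
    def test_200_gy_maps_to_one_and_400_to_two(self):
        d = _dose(np.full((4, 4, 4), 200.0), "NC")
        np.testing.assert_allclose(normalise(d), 1.0)
        np.testing.assert_allclose(normalise(_dose(np.full((4, 4, 4), 400.0),
                                                   "NC")), 2.0)

    def test_round_trip_to_machine_precision(self, rng):
        x = rng.random((5, 5, 5)) * 500
        np.testing.assert_allclose(denormalise(normalise(x)), x, rtol=1e-15)

    def test_invalid_max_raises(self):
        with pytest.raises(ValueError):
            normalise(np.ones((2, 2, 2)), max_gy=0.0)


class TestFolds:
    def test_148_cases_five_folds_sizes(self):
        folds = make_folds(list(range(148)), 5, seed=0)
        assert sorted(len(f) for f in folds) == [29, 29, 30, 30, 30]
        assert sorted(sum(folds, [])) == list(range(148))

    def test_singleton_folds(self):
        folds = make_folds(list("abcde"), 5, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_deterministic_under_seed(self):
        assert make_folds(range(17), 5, seed=3) == make_folds(range(17), 5, seed=3)

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], 5)


class TestPatchSampling:
    def test_constant_pair_yields_constant_patches(self, rng):
        cfg = TrainingConfig.desk(patch_size=8, augment=True)
        feat = np.full((1, 16, 16, 16), 3.0)
        ref = np.full((16, 16, 16), 7.0)
        for fp, rp in sample_training_patches(feat, ref, cfg, rng, 5):
            assert np.all(fp == 3.0) and np.all(rp == 7.0)
            assert rp.shape == (8, 8, 8)

    def test_paired_transform_applied_identically(self, rng):
        # encode the reference into a feature channel: if the same transform
        # is applied to both, the channel must stay equal to the reference
        cfg = TrainingConfig.desk(patch_size=8, augment=True)
        vol = rng.random((12, 12, 12))
        feat = np.stack([vol, 2 * vol])
        for fp, rp in sample_training_patches(feat, vol, cfg, rng, 10):
            np.testing.assert_array_equal(fp[0], rp)
            np.testing.assert_array_equal(fp[1], 2 * rp)

    def test_small_volume_zero_padded_to_patch(self, rng):
        cfg = TrainingConfig.desk(patch_size=16, augment=False)
        feat = np.ones((1, 6, 6, 6))
        ref = np.ones((6, 6, 6))
        fp, rp = next(sample_training_patches(feat, ref, cfg, rng, 1))
        assert fp.shape == (1, 16, 16, 16) and rp.shape == (16, 16, 16)
        assert rp.sum() == 6 ** 3  # original content preserved, rest zeros


class TestTaskContract:
    def test_tasks_bind_states(self):
        assert CorrectionTask.AC.value == ("NC", "AC")
        assert CorrectionTask.SC.value == ("AC", "ASC")
        assert CorrectionTask.ASC.value == ("NC", "ASC")

    def test_training_rejects_mismatched_states(self):
        pair = (_dose(np.ones((8, 8, 8)), "ASC"), _dose(np.ones((8, 8, 8)), "AC"))
        with pytest.raises(TaskContractError):
            train_task([pair] * 5, CorrectionTask.AC,
                       TrainingConfig.desk(patch_size=8, epochs=1))

    def test_predict_rejects_mismatched_state(self):
        ens = RegressorEnsemble(CorrectionTask.AC, [IdentityRegressor()],
                                TrainingConfig.desk(patch_size=8))
        with pytest.raises(TaskContractError):
            predict(ens, _dose(np.ones((8, 8, 8)), "ASC"))

    def test_folds_below_two_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(folds=1)


class TestEnsembleAndSlidingWindow:
    def test_five_identical_members_equal_single(self, rng):
        cfg = TrainingConfig.desk(patch_size=8)
        vol = rng.random((14, 14, 14)) * 120
        single = RegressorEnsemble(CorrectionTask.AC, [IdentityRegressor()], cfg)
        five = RegressorEnsemble(CorrectionTask.AC,
                                 [IdentityRegressor()] * 5, cfg)
        d = _dose(vol, "NC")
        np.testing.assert_array_equal(predict(single, d).values,
                                      predict(five, d).values)

    def test_seam_free_on_constant_field(self):
        """A translation-invariant member on a constant field: sliding-window
        blending must introduce no seams (interior == border to 1e-6)."""
        cfg = TrainingConfig.desk(patch_size=8)
        member = LocalFeatureMLP(
            FeatureSpec(use_depth=False, use_physics_priors=False),
            seed=3)  # untrained: residual head is exactly identity
        const = np.full((20, 20, 20), 0.4)
        feat = member.featurise(const, (4.795,) * 3)
        out = sliding_window_predict(member, feat, cfg.patch_size)
        assert np.ptp(out) <= 1e-6
        np.testing.assert_allclose(out, 0.4, atol=1e-6)

    def test_inference_on_different_spacing_runs(self):
        cfg = TrainingConfig.desk(patch_size=8)
        ens = RegressorEnsemble(CorrectionTask.AC, [IdentityRegressor()], cfg)
        d = _dose(np.random.default_rng(0).random((9, 9, 9)), "NC",
                  spacing=4.418)
        out = predict(ens, d)
        assert out.image.shape == d.image.shape
        assert out.image.spacing == d.image.spacing
        assert out.correction_state == "AC"

    def test_prediction_clamped_non_negative(self):
        cfg = TrainingConfig.desk(patch_size=8)

        class NegativeRegressor(IdentityRegressor):
            def predict_patch(self, feat_patch):
                return np.asarray(feat_patch[0]) - 10.0

        ens = RegressorEnsemble(CorrectionTask.AC, [NegativeRegressor()], cfg)
        out = predict(ens, _dose(np.zeros((8, 8, 8)), "NC"))
        assert (out.values >= 0).all()


class TestTraining:
    def test_identity_dataset_loss_non_increase(self):
        rng = np.random.default_rng(0)
        cfg = TrainingConfig.desk(patch_size=8, epochs=2, folds=2,
                                  seed=0, use_depth=False)
        maps = [_dose(rng.random((10, 10, 10)) * 50, "NC") for _ in range(4)]
        pairs = [(m, DoseMap(m.image, "AC")) for m in maps]
        ens = train_task(pairs, CorrectionTask.AC, cfg)
        for curves in ens.history:
            assert curves["val_l1"][-1] <= curves["val_l1"][0] + 1e-9

    def test_fixed_seed_reproducible_losses(self):
        rng = np.random.default_rng(1)
        cfg = TrainingConfig.desk(patch_size=8, epochs=2, folds=2, seed=5)
        pairs = []
        for _ in range(4):
            a = rng.random((10, 10, 10)) * 50
            pairs.append((_dose(a, "NC"), _dose(a * 1.1, "AC")))
        h1 = train_task(pairs, CorrectionTask.AC, cfg).history
        h2 = train_task(pairs, CorrectionTask.AC, cfg).history
        assert h1 == h2

    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = TrainingConfig.desk(patch_size=8, epochs=1, folds=2, seed=2)
        pairs = []
        for _ in range(4):
            a = rng.random((10, 10, 10)) * 50
            pairs.append((_dose(a, "NC"), _dose(a * 1.2, "AC")))
        ens = train_task(pairs, CorrectionTask.AC, cfg)
        ens.save(tmp_path / "bundle")
        back = RegressorEnsemble.load(tmp_path / "bundle")
        d = _dose(rng.random((9, 9, 9)) * 40, "NC")
        np.testing.assert_allclose(predict(ens, d).values,
                                   predict(back, d).values, atol=1e-12)
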
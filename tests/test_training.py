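"""Training recipe: augmentation, losses, schedules, selection, determinism."""

import dataclasses
import math

import numpy as np
import pytest

from cytoseg.core import TaskType
from cytoseg.models import ModelSpec
from cytoseg.synthetic import SyntheticConfig, generate_sample
from cytoseg.training import (AugmentConfig, TrainConfig, TrainingHistory,
                              augment, lookahead_update, lr_at_epoch,
                              select_best, smooth_labels, train_model,
                              weighted_bce)

NO_PHOTO = AugmentConfig(brightness_contrast_p=0, blur_p=0, hue_saturation_p=0)


class TestSmoothLabels:
    def test_eps_zero_is_identity(self):
        m = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(smooth_labels(m, 0.0), m.astype(float))

    def test_symmetric_targets_at_default_eps(self):
        m = np.array([0, 1], dtype=np.uint8)
        np.testing.assert_allclose(smooth_labels(m, 0.1), [0.05, 0.95])

    @pytest.mark.parametrize("eps", [-0.1, 1.0, 2.0])
    def test_eps_out_of_range(self, eps):
        with pytest.raises(ValueError):
            smooth_labels(np.zeros((2, 2)), eps)


class TestWeightedBce:
    def test_closed_forms(self):
        p = np.array([[0.5]])
        assert weighted_bce(p, np.array([[1.0]]), 8.0) == pytest.approx(8 * math.log(2))
        assert weighted_bce(p, np.array([[0.0]]), 8.0) == pytest.approx(math.log(2))

    def test_perfect_hard_targets_near_zero(self):
        t = np.array([[0.0, 1.0]])
        loss = weighted_bce(t, t, 3.0)  # probs clamp at 1e-7
        assert loss < 1e-5

    def test_reduces_to_plain_bce_at_weight_one(self, rng):
        p = rng.uniform(0.01, 0.99, (16, 16))
        t = rng.integers(0, 2, (16, 16)).astype(float)
        direct = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert weighted_bce(p, t, 1.0) == pytest.approx(direct, rel=1e-10)

    def test_monotone_in_probability(self):
        grid = np.linspace(0.01, 0.99, 50)
        pos = [weighted_bce(np.array([[g]]), np.array([[1.0]]), 2.0) for g in grid]
        neg = [weighted_bce(np.array([[g]]), np.array([[0.0]]), 2.0) for g in grid]
        assert all(a >= b for a, b in zip(pos, pos[1:]))   # decreasing for t=1
        assert all(a <= b for a, b in zip(neg, neg[1:]))   # increasing for t=0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_bce(np.zeros((2, 2)), np.zeros((3, 3)), 1.0)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch, expected", [
        (0, 1e-3), (5, 1e-3), (6, 1e-4), (11, 1e-4),
        (12, 1e-5), (17, 1e-5), (18, 1e-6), (19, 1e-6),
    ])
    def test_staged_decay_over_20_epochs(self, epoch, expected):
        cfg = TrainConfig(epochs=20)
        assert lr_at_epoch(epoch, cfg) == pytest.approx(expected)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_at_epoch(20, TrainConfig(epochs=20))

    def test_no_milestones_constant(self):
        cfg = TrainConfig(epochs=3, milestones=())
        assert all(lr_at_epoch(e, cfg) == 1e-3 for e in range(3))


class TestLookaheadUpdate:
    def test_sync_step_interpolates_and_resets(self):
        fast, slow = lookahead_update(2.0, 0.0, step=5, k=5, alpha=0.5)
        assert fast == 1.0 and slow == 1.0

    def test_non_sync_step_is_identity(self):
        fast, slow = lookahead_update(2.0, 0.0, step=3, k=5, alpha=0.5)
        assert fast == 2.0 and slow == 0.0

    def test_alpha_one_jumps_to_fast(self):
        fast, slow = lookahead_update(2.0, 0.0, step=5, k=5, alpha=1.0)
        assert slow == 2.0 and fast == 2.0

    @pytest.mark.parametrize("kwargs", [{"k": 0}, {"alpha": -0.1}, {"alpha": 1.5}])
    def test_invalid_arguments(self, kwargs):
        args = {"k": 5, "alpha": 0.5}
        args.update(kwargs)
        with pytest.raises(ValueError):
            lookahead_update(1.0, 0.0, step=1, **args)


class TestAugment:
    @pytest.fixture()
    def sample(self, tiny_samples):
        return tiny_samples[0]

    def test_forced_flips_move_image_and_masks_together(self, sample):
        cfg = dataclasses.replace(NO_PHOTO, flip_p=1.0)  # h then v flip
        out = augment(sample, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(out.image, sample.image[::-1, ::-1])
        np.testing.assert_array_equal(out.cytoplasm_mask,
                                      sample.cytoplasm_mask[::-1, ::-1])
        np.testing.assert_array_equal(out.nucleus_mask,
                                      sample.nucleus_mask[::-1, ::-1])

    def test_photometric_transforms_leave_masks_untouched(self, sample):
        cfg = AugmentConfig(flip_p=0.0, brightness_contrast_p=1.0, blur_p=1.0,
                            hue_saturation_p=1.0)
        out = augment(sample, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(out.cytoplasm_mask, sample.cytoplasm_mask)
        np.testing.assert_array_equal(out.nucleus_mask, sample.nucleus_mask)
        assert (out.image != sample.image).any()

    def test_masks_stay_binary_and_deterministic(self, sample):
        a = augment(sample, np.random.default_rng(7))
        b = augment(sample, np.random.default_rng(7))
        np.testing.assert_array_equal(a.image, b.image)
        assert set(np.unique(a.cytoplasm_mask)) <= {0, 1}
        assert set(np.unique(a.nucleus_mask)) <= {0, 1}

    def test_geometric_correspondence_on_coordinate_grid(self):
        """Encode pixel coordinates in the masks: wherever the image grid
        moves under the geometric transform, the masks move identically."""
        h, w = 16, 16
        coord = (np.arange(h * w).reshape(h, w) % 2).astype(np.uint8)
        img = np.dstack([coord * 255] * 3).astype(np.uint8)
        from cytoseg.core import ImageSample
        s = ImageSample("grid", img, coord, coord)
        cfg = dataclasses.replace(NO_PHOTO, flip_p=1.0)
        out = augment(s, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(out.image[..., 0] // 255, out.cytoplasm_mask)


class TestSelectBest:
    def _run(self, losses):
        h = TrainingHistory(val_loss=list(losses),
                            train_loss=[0] * len(losses),
                            val_dice=[0] * len(losses))
        return (object(), h)

    def test_minimum_validation_loss_wins(self):
        runs = [self._run([0.31]), self._run([0.28]), self._run([0.30])]
        assert select_best(runs) is runs[1]

    def test_single_run_identity(self):
        runs = [self._run([0.5])]
        assert select_best(runs) is runs[0]

    def test_tie_broken_by_earliest(self):
        runs = [self._run([0.3]), self._run([0.3]), self._run([0.4])]
        assert select_best(runs) is runs[0]

    def test_minimum_over_epochs_not_final(self):
        runs = [self._run([0.2, 0.9]), self._run([0.5, 0.25])]
        assert select_best(runs) is runs[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


def _small_data(n_train=24, n_val=6, seed=31):
    cfg = SyntheticConfig.tiny(seed=seed)
    samples = [generate_sample(cfg, i) for i in range(n_train + n_val)]
    return samples[:n_train], samples[n_train:]


class TestTrainModel:
    SPEC = ModelSpec("unet", "resnet34", tiny=True)

    def test_zero_epochs_returns_initialized_model(self):
        train, val = _small_data(4, 2)
        cfg = TrainConfig(task=TaskType.CYTOPLASM, epochs=0, n_runs=1, seed=0)
        model, history = train_model(self.SPEC, cfg, train, val)
        assert history.val_loss == [] and history.train_loss == []
        assert model.predict_proba(train[0].image[None]).shape == (1, 64, 64)

    def test_empty_sets_rejected(self):
        train, val = _small_data(4, 2)
        cfg = TrainConfig(epochs=1, n_runs=1)
        with pytest.raises(ValueError):
            train_model(self.SPEC, cfg, [], val)

    def test_same_seed_reproduces_validation_loss(self):
        train, val = _small_data(12, 4)
        cfg = TrainConfig(task=TaskType.CYTOPLASM, epochs=1, batch_size=4,
                          milestones=(), n_runs=1, seed=42)
        _, h1 = train_model(self.SPEC, cfg, train, val)
        _, h2 = train_model(self.SPEC, cfg, train, val)
        assert h1.val_loss == h2.val_loss
        assert h1.train_loss == h2.train_loss

    def test_short_training_beats_trivial_predictors(self):
        train, val = _small_data(48, 8)
        cfg = TrainConfig(task=TaskType.CYTOPLASM, epochs=2, batch_size=8,
                          base_lr=5e-3, milestones=(), n_runs=1, seed=0)
        model, history = train_model(self.SPEC, cfg, train, val)
        # trivial baselines on the validation set
        pos = sum(s.cytoplasm_mask.sum() for s in val)
        tot = sum(s.cytoplasm_mask.size for s in val)
        all_positive_dice = 2 * pos / (pos + tot)
        assert history.val_dice[-1] > max(all_positive_dice, 0.0) + 0.05

    def test_history_lengths_match_epochs(self):
        train, val = _small_data(8, 2)
        cfg = TrainConfig(task=TaskType.NUCLEUS, epochs=2, batch_size=4,
                          milestones=(), n_runs=1, seed=1)
        _, h = train_model(self.SPEC, cfg, train, val)
        assert len(h.train_loss) == len(h.val_loss) == len(h.val_dice) == 2
        assert all(np.isfinite(h.train_loss))

    def test_history_csv(self, tmp_path):
        h = TrainingHistory(train_loss=[0.5], val_loss=[0.4], val_dice=[0.8])
        h.to_csv(tmp_path / "h.csv")
        text = (tmp_path / "h.csv").read_text().splitlines()
        assert text[0] == "epoch,train_loss,val_loss,val_dice"
        assert text[1].startswith("0,0.5")


class TestTrainConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"pos_weight": 0.5}, {"label_smooth_eps": 1.0},
        {"milestones": (0.6, 0.3)}, {"milestones": (0.0, 0.5)},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)

    def test_task_dependent_default_weight(self):
        assert TrainConfig(task=TaskType.CYTOPLASM).effective_pos_weight == 1.0
        assert TrainConfig(task=TaskType.NUCLEUS).effective_pos_weight == 8.0
        assert TrainConfig(task=TaskType.NUCLEUS, pos_weight=3.0).effective_pos_weight == 3.0
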
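"""Loss functions and the training loop's contracts (fast variants)."""

import copy

import numpy as np
import pytest

from iousseg.model import ModelConfig
from iousseg.preprocess import ClipRecord, make_patient_split
from iousseg.train import (TrainConfig, collect_partition, compute_loss,
                           train_vessel_model)

SMALL = dict(encoder_filters=(4, 4, 8, 8, 16), decoder_filters=(8, 8, 4, 4),
             head_filters=4, attention_channels=16)


def _toy_clips(n_patients=4, frames=6, side=32, seed=0):
    """Separable synthetic clips: a dark square on a bright background."""
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n_patients):
        fs, ms, ws = [], [], []
        for _ in range(frames):
            y, x = rng.integers(4, side - 12, 2)
            frame = np.full((side, side), 0.7, np.float32)
            frame += rng.normal(0, 0.05, frame.shape).astype(np.float32)
            mask = np.zeros((side, side), np.uint8)
            mask[y:y + 8, x:x + 8] = 1
            frame[mask == 1] *= 0.15
            fs.append(np.clip(frame, 0, 1))
            ms.append(mask)
            ws.append(mask.astype(np.float32))
        clips.append(ClipRecord(f"p{i}", "IVC", f"c{i}", fs, ms, ws))
    return clips


class TestComputeLoss:
    def test_exact_match_gives_zero_dice_loss(self):
        mask = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert compute_loss(mask, mask, "dice") == pytest.approx(0.0, abs=1e-5)

    def test_half_probability_2x2_example(self):
        """p=0.5 everywhere, 2 of 4 true: 1 - (2*1+eps)/(2+2+eps) ~ 0.5."""
        prob = np.full((2, 2), 0.5)
        mask = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert compute_loss(prob, mask, "dice") == pytest.approx(0.5, abs=1e-6)

    def test_losses_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            prob = rng.random((6, 6))
            mask = (rng.random((6, 6)) > 0.5).astype(float)
            for kind in ("dice", "bce", "bce+dice"):
                assert compute_loss(prob, mask, kind) >= 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            compute_loss(np.zeros((4, 4)), np.zeros((4, 4)), "focal")


class TestTrainConfig:
    def test_paper_recipe_defaults(self):
        tc = TrainConfig()
        assert tc.optimizer == "adam"
        assert tc.learning_rate == pytest.approx(1e-3)
        assert tc.batch_size == 16
        assert tc.epochs == 100
        assert tc.augmentation == "none"

    def test_augmentation_locked_off(self):
        with pytest.raises(ValueError):
            TrainConfig(augmentation="flip")


@pytest.fixture(scope="module")
def run():
    clips = _toy_clips()
    split = make_patient_split([c.patient_id for c in clips],
                               (0.5, 0.25, 0.25), seed=0)
    mc = ModelConfig(input_side=32, seed=0, **SMALL)
    tc = TrainConfig(epochs=6, batch_size=8, seed=0)
    model, hist = train_vessel_model(clips, split, mc, tc)
    return clips, split, mc, tc, model, hist


class TestTrainingLoop:

    def test_loss_decreases_over_first_epochs(self, run):
        _, _, _, _, _, hist = run
        assert hist.train_loss.iloc[4] < hist.train_loss.iloc[0]

    def test_history_one_row_per_epoch(self, run):
        *_, hist = run
        assert list(hist.epoch) == list(range(6))
        assert {"train_loss", "val_dice", "val_loss", "seconds"} <= set(hist)

    def test_training_is_deterministic(self, run):
        clips, split, mc, tc, _, hist = run
        _, hist2 = train_vessel_model(clips, split, mc, tc)
        assert hist2.val_dice.tolist() == hist.val_dice.tolist()
        assert hist2.train_loss.tolist() == hist.train_loss.tolist()

    def test_frame_order_across_clips_is_irrelevant_to_the_sample_set(self, run):
        """Frames are independent samples: permuting clip membership of the
        same frames leaves the training set (and seeded run) unchanged."""
        clips, split, mc, tc, _, hist = run
        # re-pack the same frames into differently-sized clips
        tr = [c for c in clips if c.patient_id in split.train_patients]
        frames = [(f, m, w) for c in tr
                  for f, m, w in zip(c.frames, c.masks, c.weight_maps)]
        half = len(frames) // 2
        repacked = [
            ClipRecord(tr[0].patient_id, "IVC", "r0",
                       [f for f, _, _ in frames[:half]],
                       [m for _, m, _ in frames[:half]],
                       [w for _, _, w in frames[:half]]),
            ClipRecord(tr[1].patient_id, "IVC", "r1",
                       [f for f, _, _ in frames[half:]],
                       [m for _, m, _ in frames[half:]],
                       [w for _, _, w in frames[half:]]),
        ]
        others = [c for c in clips if c.patient_id not in split.train_patients]
        _, hist3 = train_vessel_model(repacked + others, split, mc, tc)
        assert hist3.val_dice.tolist() == hist.val_dice.tolist()

    def test_mixed_vessels_rejected(self, run):
        clips, split, mc, tc, *_ = run
        bad = copy.copy(clips[0])
        bad.vessel_label = "RHV"
        with pytest.raises(ValueError):
            train_vessel_model([bad] + clips[1:], split, mc, tc)

    def test_empty_train_partition_rejected(self, run):
        clips, _, mc, tc, *_ = run
        from iousseg.preprocess import DatasetSplit
        ids = [c.patient_id for c in clips]
        split = DatasetSplit(frozenset(), frozenset(ids[:1]), frozenset(ids[1:]))
        with pytest.raises(ValueError):
            train_vessel_model(clips, split, mc, tc)

    def test_missing_weight_maps_rejected(self, run):
        clips, split, mc, tc, *_ = run
        bad = [copy.copy(c) for c in clips]
        for c in bad:
            c.weight_maps = None
        with pytest.raises(ValueError):
            train_vessel_model(bad, split, mc, tc)


def test_collect_partition_respects_patient_assignment():
    clips = _toy_clips(n_patients=5)
    split = make_patient_split([c.patient_id for c in clips], seed=1)
    tr = collect_partition(clips, split, "train")
    te = collect_partition(clips, split, "test")
    n_train_patients = len(split.train_patients)
    assert len(tr[0]) == n_train_patients * 6
    assert len(tr[0]) + len(te[0]) + len(
        collect_partition(clips, split, "val")[0]) == 5 * 6
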
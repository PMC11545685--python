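"""Quality filter, normalization, clip splitting and patient-level splits."""

import numpy as np
import pytest

from iousseg.preprocess import (DatasetSplit, QualityThresholds,
                                assess_frame_quality, make_patient_split,
                                normalize_frame, normalize_mask,
                                split_clip_on_structural_change)


class TestQualityFilter:
    def test_all_black_frame_flagged(self):
        v = assess_frame_quality(np.zeros((256, 256), np.uint8))
        assert not v.keep and v.reason == "blackness"

    def test_empty_mask_flagged_as_no_target(self):
        rng = np.random.default_rng(0)
        frame = (rng.random((64, 64)) * 200 + 30).astype(np.uint8)
        v = assess_frame_quality(frame, mask=np.zeros((64, 64), np.uint8))
        assert not v.keep and v.reason == "no_target"

    def test_blackness_takes_priority_over_no_target(self):
        v = assess_frame_quality(np.zeros((64, 64), np.uint8),
                                 mask=np.zeros((64, 64), np.uint8))
        assert v.reason == "blackness"

    def test_checkerboard_vs_blurred_at_derived_midpoint(self):
        """Threshold fixed between the two sharpness statistics separates them."""
        from scipy.ndimage import gaussian_filter, laplace
        tile = np.kron([[0, 1] * 16, [1, 0] * 16] * 16, np.ones((8, 8)))
        sharp = (tile[:256, :256] * 255).astype(np.uint8)
        blurred = gaussian_filter(sharp.astype(float), 8.0).astype(np.uint8)
        v_sharp = float(laplace(sharp / 255.0).var())
        v_blur = float(laplace(blurred / 255.0).var())
        assert v_sharp > v_blur
        th = QualityThresholds(laplacian_var_min=(v_sharp + v_blur) / 2)
        assert assess_frame_quality(sharp, thresholds=th).keep
        assert assess_frame_quality(blurred, thresholds=th).reason == "blurry"

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError):
            assess_frame_quality(np.zeros((4, 4, 3), np.uint8))


class TestNormalize:
    def test_constant_extremes(self):
        f = normalize_frame(np.full((256, 256), 255, np.uint8))
        assert np.allclose(f, 1.0)
        assert np.allclose(normalize_frame(np.zeros((256, 256), np.uint8)), 0.0)

    def test_resize_to_canonical_side(self):
        f = normalize_frame(np.random.default_rng(0).integers(
            0, 256, (512, 512)).astype(np.uint8))
        assert f.shape == (256, 256)
        assert f.dtype == np.float32 and f.min() >= 0 and f.max() <= 1

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(0, 256, (256, 256)).astype(np.uint8)
        once = normalize_frame(raw)
        twice = normalize_frame(once)
        np.testing.assert_allclose(once, twice, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_frame(np.zeros((0, 0)))

    def test_mask_stays_binary_after_resize(self):
        mask = np.zeros((100, 100), np.uint8)
        mask[30:60, 20:70] = 255
        out = normalize_mask(mask, side=256)
        assert set(np.unique(out)) <= {0, 1}
        assert out.shape == (256, 256)


class TestClipSplitting:
    def test_identical_frames_one_range(self):
        frames = [np.full((8, 8), 50, np.uint8)] * 10
        assert split_clip_on_structural_change(frames, 1.0) == [(0, 10)]

    def test_step_change_cuts_at_boundary(self):
        frames = ([np.full((8, 8), 10, np.uint8)] * 5
                  + [np.full((8, 8), 200, np.uint8)] * 5)
        assert split_clip_on_structural_change(frames, 50.0) == [(0, 5), (5, 10)]

    def test_single_frame(self):
        assert split_clip_on_structural_change(
            [np.zeros((4, 4), np.uint8)], 10.0) == [(0, 1)]

    def test_ranges_always_partition(self):
        rng = np.random.default_rng(2)
        frames = [rng.integers(0, 256, (16, 16)).astype(np.uint8)
                  for _ in range(20)]
        ranges = split_clip_on_structural_change(frames, 30.0)
        assert ranges[0][0] == 0 and ranges[-1][1] == 20
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            assert b == c and a < b


class TestPatientSplit:
    def test_22_patients_round_to_13_2_7(self):
        ids = [f"p{i}" for i in range(22)]
        s = make_patient_split(ids, seed=0)
        sizes = (len(s.train_patients), len(s.val_patients), len(s.test_patients))
        assert sizes == (13, 2, 7)
        assert s.train_patients | s.val_patients | s.test_patients == set(ids)

    def test_three_patients_one_each(self):
        s = make_patient_split(["a", "b", "c"], seed=1)
        assert (len(s.train_patients), len(s.val_patients),
                len(s.test_patients)) == (1, 1, 1)

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(10)]
        assert make_patient_split(ids, seed=7).train_patients == \
            make_patient_split(ids, seed=7).train_patients

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_patient_split(["a", "b"])

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(frozenset("ab"), frozenset("bc"), frozenset("d"))

    def test_no_patient_in_two_partitions_many_seeds(self):
        ids = [f"p{i}" for i in range(17)]
        for seed in range(100):
            s = make_patient_split(ids, seed=seed)
            assert not s.train_patients & s.val_patients
            assert not s.train_patients & s.test_patients
            assert not s.val_patients & s.test_patients
            assert len(s.train_patients | s.val_patients | s.test_patients) == 17

    def test_roundtrip_json(self, tmp_path):
        s = make_patient_split([f"p{i}" for i in range(8)], seed=3)
        s.to_json(tmp_path / "split.json")
        s2 = DatasetSplit.from_json(tmp_path / "split.json")
        assert s2.train_patients == s.train_patients
        assert s2.test_patients == s.test_patients
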
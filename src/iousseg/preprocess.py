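"""Raw-clip preprocessing: quality filtering, normalization, splitting.

Raw intraoperative ultrasound recordings contain frames with no usable
anatomy: near-black frames captured while the probe is off the organ,
frames in which the target vessel has left the imaging plane, and frames
smeared by probe motion. The quality filter flags these three classes from
cheap image statistics. Surviving frames are resized to the model grid and
scaled to [0, 1]; recordings are cut into shorter clips wherever the
inter-frame intensity difference indicates a significant structural change;
and patients are partitioned into train/validation/test sets so that no
patient ever contributes frames to two partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import laplace
from skimage.transform import resize

__all__ = [
    "QualityThresholds",
    "QualityVerdict",
    "DatasetSplit",
    "ClipRecord",
    "assess_frame_quality",
    "normalize_frame",
    "normalize_mask",
    "split_clip_on_structural_change",
    "make_patient_split",
    "load_raw_dataset",
    "quality_report",
]


@dataclass
class QualityThresholds:
    """Cutoffs for the three degenerate-frame classes.

    ``blackness``: a frame is discarded when at least ``black_fraction`` of
    its pixels fall below ``dark_intensity`` (8-bit units); requiring 95%
    of the pixels dark keeps the test robust to a few bright artifacts.
    ``blurriness``: variance of a 3x3 Laplacian response on the [0, 1]
    grayscale; speckle-bearing ultrasound frames score orders of magnitude
    above defocused/motion-smeared ones, so the default separates the two
    populations by a wide margin (calibrated on the phantom corpus).
    """

    dark_intensity: int = 10
    black_fraction: float = 0.95
    laplacian_var_min: float = 1e-4


@dataclass
class QualityVerdict:
    keep: bool
    reason: str  # ok | blackness | no_target | blurry
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.keep == (self.reason == "ok")


@dataclass
class DatasetSplit:
    """Patient-level partition; clips inherit their patient's partition."""

    train_patients: frozenset
    val_patients: frozenset
    test_patients: frozenset

    def __post_init__(self):
        parts = [self.train_patients, self.val_patients, self.test_patients]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split partitions must be disjoint")

    def partition_of(self, patient_id: str) -> str:
        if patient_id in self.train_patients:
            return "train"
        if patient_id in self.val_patients:
            return "val"
        if patient_id in self.test_patients:
            return "test"
        raise KeyError(patient_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train": sorted(self.train_patients),
                       "val": sorted(self.val_patients),
                       "test": sorted(self.test_patients)}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(frozenset(d["train"]), frozenset(d["val"]), frozenset(d["test"]))


@dataclass
class ClipRecord:
    """Model-ready clip: normalized frames with aligned binary masks."""

    patient_id: str
    vessel_label: str
    clip_id: str
    frames: list  # float32 (S, S) in [0, 1]
    masks: list  # uint8 (S, S) in {0, 1}
    weight_maps: list | None = None

    def __post_init__(self):
        if len(self.frames) != len(self.masks):
            raise ValueError("frames and masks must align")
        for m in self.masks:
            vals = np.unique(m)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("masks must be strictly {0,1}-valued")

    def __len__(self):
        return len(self.frames)


def _check_raw(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    if np.issubdtype(frame.dtype, np.floating):
        if frame.min() < 0 or frame.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")
    return frame


def assess_frame_quality(
    frame: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: QualityThresholds | None = None,
) -> QualityVerdict:
    """Classify one raw 8-bit frame as ok / blackness / no_target / blurry.

    Checks are ordered: an (almost) all-black frame is reported as
    blackness even though it also has no visible target.
    """
    th = thresholds or QualityThresholds()
    frame = _check_raw(frame)
    f = frame.astype(np.float32)
    black_frac = float((f < th.dark_intensity).mean())
    lap_var = float(laplace(f / 255.0).var())
    stats = {"black_fraction": black_frac, "laplacian_variance": lap_var}
    if black_frac >= th.black_fraction:
        return QualityVerdict(False, "blackness", stats)
    if mask is not None and np.asarray(mask).sum() == 0:
        return QualityVerdict(False, "no_target", stats)
    if lap_var < th.laplacian_var_min:
        return QualityVerdict(False, "blurry", stats)
    return QualityVerdict(True, "ok", stats)


def normalize_frame(frame: np.ndarray, side: int = 256) -> np.ndarray:
    """Resize to ``side`` x ``side`` (bilinear) and scale 8-bit to [0, 1].

    Float input already in [0, 1] is passed through unscaled, which makes
    the operation idempotent on previously normalized frames.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("expected a non-empty 2-D frame")
    if np.issubdtype(frame.dtype, np.floating) and frame.size and frame.max() <= 1.0:
        out = frame.astype(np.float32)
    else:
        _check_raw(frame)
        out = frame.astype(np.float32) / 255.0
    if out.shape != (side, side):
        out = resize(out, (side, side), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True).astype(np.float32)
    return np.clip(out, 0.0, 1.0)


def normalize_mask(mask: np.ndarray, side: int = 256) -> np.ndarray:
    """Nearest-neighbour resize keeping the mask strictly binary."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("expected a non-empty 2-D mask")
    binary = (mask > (127 if mask.dtype == np.uint8 and mask.max() > 1 else 0))
    if binary.shape != (side, side):
        binary = resize(binary.astype(np.uint8), (side, side), order=0,
                        anti_aliasing=False, preserve_range=True) > 0.5
    return binary.astype(np.uint8)


def split_clip_on_structural_change(
    frames: list, mean_abs_diff_threshold: float = 25.0
) -> list[tuple[int, int]]:
    """Cut a recording into clips at large inter-frame intensity changes.

    Returns half-open index ranges that partition ``[0, n_frames)``. A cut
    is placed before frame ``t`` whenever the mean absolute intensity
    difference between frames ``t-1`` and ``t`` (8-bit units) exceeds the
    threshold — an automated proxy for the structural-change judgement a
    radiologist would make.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    ranges, start = [], 0
    prev = np.asarray(frames[0], dtype=np.float32)
    for t in range(1, len(frames)):
        cur = np.asarray(frames[t], dtype=np.float32)
        if float(np.abs(cur - prev).mean()) > mean_abs_diff_threshold:
            ranges.append((start, t))
            start = t
        prev = cur
    ranges.append((start, len(frames)))
    return ranges


def make_patient_split(
    patient_ids: list,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic patient-level 60/10/30 split.

    Partition sizes come from largest-remainder rounding of the fractions
    (so 22 patients give 13/2/7); every partition is guaranteed at least
    one patient, borrowing from the largest partition if rounding left one
    empty. Membership is a seeded permutation.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 patients for a 3-way split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    quotas = [f * n for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for k in sorted(range(3), key=lambda i: -remainders[i])[: n - sum(sizes)]:
        sizes[k] += 1
    while min(sizes) == 0:
        sizes[int(np.argmax(sizes))] -= 1
        sizes[int(np.argmin(sizes))] += 1
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    train = frozenset(order[: sizes[0]])
    val = frozenset(order[sizes[0]: sizes[0] + sizes[1]])
    test = frozenset(order[sizes[0] + sizes[1]:])
    return DatasetSplit(train, val, test)


# --------------------------------------------------------------------- disk


def load_raw_dataset(
    root,
    side: int = 256,
    thresholds: QualityThresholds | None = None,
    apply_quality_filter: bool = True,
) -> tuple[list[ClipRecord], pd.DataFrame]:
    """Read the on-disk clip layout into normalized ClipRecords.

    Layout: ``<root>/<patient>/<vessel>/<clip>/frame_%05d.png`` with
    parallel ``mask_%05d.png`` and optional ``wmap_%05d.png``. Returns the
    kept clips and a per-frame quality report (clip, frame, verdict,
    statistics). Frames failing the quality filter are dropped from the
    records but present in the report.
    """
    import imageio.v3 as iio

    root = Path(root)
    records, rows = [], []
    for patient_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for vessel_dir in sorted(p for p in patient_dir.iterdir() if p.is_dir()):
            for clip_dir in sorted(p for p in vessel_dir.iterdir() if p.is_dir()):
                frames, masks, wmaps = [], [], []
                has_wmap = True
                for fpath in sorted(clip_dir.glob("frame_*.png")):
                    idx = int(fpath.stem.split("_")[1])
                    raw = iio.imread(fpath)
                    mpath = clip_dir / f"mask_{idx:05d}.png"
                    rmask = iio.imread(mpath) if mpath.exists() else None
                    verdict = (assess_frame_quality(raw, rmask, thresholds)
                               if apply_quality_filter
                               else QualityVerdict(True, "ok"))
                    rows.append({
                        "patient_id": patient_dir.name,
                        "vessel": vessel_dir.name,
                        "clip_id": clip_dir.name, "frame_index": idx,
                        "keep": verdict.keep, "reason": verdict.reason,
                        **verdict.stats,
                    })
                    if not verdict.keep:
                        continue
                    frames.append(normalize_frame(raw, side))
                    masks.append(normalize_mask(rmask, side)
                                 if rmask is not None
                                 else np.zeros((side, side), np.uint8))
                    wpath = clip_dir / f"wmap_{idx:05d}.png"
                    if wpath.exists():
                        wmaps.append(normalize_frame(iio.imread(wpath), side))
                    else:
                        has_wmap = False
                if frames:
                    records.append(ClipRecord(
                        patient_dir.name, vessel_dir.name, clip_dir.name,
                        frames, masks, wmaps if has_wmap else None))
    return records, pd.DataFrame(rows)


def quality_report(report: pd.DataFrame, path) -> None:
    """Write the per-frame quality verdicts as CSV."""
    report.to_csv(path, index=False)
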
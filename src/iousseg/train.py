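"""Per-vessel training loop with strict patient-level isolation.

One binary network is trained per vessel label on individual frames (not
sequences), following the recipe the architecture was designed around:
Adam at learning rate 1e-3, batch size 16, no data augmentation, ReLU
activations, dropout fixed at zero. Patients are partitioned before any
frame is seen, so no patient contributes frames to more than one of
train/validation/test. Model selection keeps the checkpoint with the best
validation Dice.

The default loss is the sum of pixel-wise binary cross-entropy and soft
Dice loss, a standard pairing for class-imbalanced binary segmentation;
either component can be used alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelConfig, WeightedUNet, build_model
from .nn import Adam
from .preprocess import ClipRecord, DatasetSplit

__all__ = ["TrainConfig", "compute_loss", "train_vessel_model",
           "fit_single_batch", "collect_partition"]

EPS = 1e-6  # Dice denominators: keeps empty-mask frames finite

LOSS_KINDS = ("dice", "bce", "bce+dice")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 100
    augmentation: str = "none"
    loss: str = "bce+dice"
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.augmentation != "none":
            raise ValueError("augmentation must be 'none' for this recipe")
        if self.loss not in LOSS_KINDS:
            raise ValueError(f"loss must be one of {LOSS_KINDS}")


# ------------------------------------------------------------------- losses


def _soft_dice_terms(prob: np.ndarray, mask: np.ndarray):
    axes = tuple(range(1, prob.ndim))
    inter = (prob * mask).sum(axis=axes)
    sums = prob.sum(axis=axes) + mask.sum(axis=axes)
    return inter, sums


def compute_loss(prob: np.ndarray, mask: np.ndarray, kind: str = "bce+dice") -> float:
    """Scalar training loss between a probability map and a binary mask.

    ``dice`` is the per-sample soft Dice loss 1 - (2*sum(p*m)+eps) /
    (sum(p)+sum(m)+eps) averaged over the batch; ``bce`` is mean pixel-wise
    binary cross-entropy; ``bce+dice`` is their sum. Inputs may be a single
    frame (2-D) or a batch.
    """
    if kind not in LOSS_KINDS:
        raise ValueError(f"unknown loss kind {kind!r}")
    prob = np.asarray(prob, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if prob.shape != mask.shape:
        raise ValueError("prob and mask must share one grid")
    if prob.ndim == 2:
        prob, mask = prob[None], mask[None]
    total = 0.0
    if kind in ("dice", "bce+dice"):
        inter, sums = _soft_dice_terms(prob, mask)
        total += float(np.mean(1.0 - (2.0 * inter + EPS) / (sums + EPS)))
    if kind in ("bce", "bce+dice"):
        p = np.clip(prob, 1e-7, 1.0 - 1e-7)
        total += float(np.mean(-(mask * np.log(p) + (1.0 - mask) * np.log1p(-p))))
    return total


def _loss_and_logit_grad(prob: np.ndarray, mask: np.ndarray, kind: str):
    """Loss value and its gradient w.r.t. the pre-sigmoid logits."""
    n = prob.shape[0]
    grad = np.zeros_like(prob)
    loss = 0.0
    if kind in ("bce", "bce+dice"):
        npix = prob.size
        p = np.clip(prob.astype(np.float64), 1e-7, 1.0 - 1e-7)
        loss += float(np.mean(-(mask * np.log(p) + (1.0 - mask) * np.log1p(-p))))
        grad += (prob - mask) / npix  # sigmoid + BCE collapse
    if kind in ("dice", "bce+dice"):
        inter, sums = _soft_dice_terms(prob.astype(np.float64),
                                       mask.astype(np.float64))
        num = 2.0 * inter + EPS
        den = sums + EPS
        loss += float(np.mean(1.0 - num / den))
        shape = (n,) + (1,) * (prob.ndim - 1)
        dp = -(2.0 * mask * den.reshape(shape) - num.reshape(shape)) / (
            den.reshape(shape) ** 2) / n
        grad += (dp * prob * (1.0 - prob)).astype(np.float32)
    return loss, grad.astype(np.float32)


def _batch_dice(prob: np.ndarray, mask: np.ndarray, threshold: float = 0.5):
    """Mean hard Dice over a batch at the given threshold."""
    pred = prob >= threshold
    m = mask > 0.5
    axes = tuple(range(1, prob.ndim))
    inter = (pred & m).sum(axis=axes)
    sums = pred.sum(axis=axes) + m.sum(axis=axes)
    return float(np.mean(np.where(sums > 0, 2.0 * inter / np.maximum(sums, 1), 1.0)))


# ------------------------------------------------------------- data plumbing


def collect_partition(
    clips: list[ClipRecord], split: DatasetSplit, partition: str
):
    """Stack frames/weight maps/masks of one split partition into batches."""
    frames, wmaps, masks = [], [], []
    for clip in clips:
        if split.partition_of(clip.patient_id) != partition:
            continue
        if clip.weight_maps is None:
            raise ValueError(
                f"clip {clip.clip_id} has no weight maps; the model has no "
                "map-free mode")
        frames.extend(clip.frames)
        wmaps.extend(clip.weight_maps)
        masks.extend(clip.masks)
    if not frames:
        return (np.zeros((0, 1, 1, 1), np.float32),) * 3
    to4 = lambda xs, dt: np.stack(xs).astype(dt)[..., None]
    return (to4(frames, np.float32), to4(wmaps, np.float32),
            to4(masks, np.float32))


def _forward_batched(model, frames, wmaps, batch_size=16):
    out = []
    for i in range(0, len(frames), batch_size):
        out.append(model.forward(frames[i:i + batch_size],
                                 wmaps[i:i + batch_size], train=False))
    return np.concatenate(out) if out else np.zeros_like(frames)


# ------------------------------------------------------------ training loops


def fit_single_batch(
    model: WeightedUNet,
    frames: np.ndarray,
    wmaps: np.ndarray,
    masks: np.ndarray,
    steps: int,
    tconfig: TrainConfig | None = None,
) -> float:
    """Repeatedly optimise one batch; returns the final training Dice.

    The standard memorisation sanity check: a correctly wired network and
    loss must be able to drive the training Dice close to 1 on a batch it
    sees at every step.
    """
    tc = tconfig or TrainConfig()
    opt = Adam(model.params(), lr=tc.learning_rate)
    for _ in range(steps):
        prob = model.forward(frames, wmaps, train=True)
        _, grad = _loss_and_logit_grad(prob, masks, tc.loss)
        opt.zero_grad()
        model.backward(grad)
        opt.step()
    prob = model.forward(frames, wmaps, train=False)
    return _batch_dice(prob, masks)


def train_vessel_model(
    clips: list[ClipRecord],
    split: DatasetSplit,
    mconfig: ModelConfig | None = None,
    tconfig: TrainConfig | None = None,
    wmaps_override: dict | None = None,
) -> tuple[WeightedUNet, pd.DataFrame]:
    """Train one binary vessel model on the train partition of ``clips``.

    All clips must carry the same vessel label. Frames are treated as
    independent samples and shuffled across clips each epoch (seeded).
    Validation Dice is computed each epoch on the validation partition and the
    best-validation checkpoint is restored before returning. Returns the
    model and a per-epoch history table.
    """
    import time

    mc = mconfig or ModelConfig()
    tc = tconfig or TrainConfig()
    vessels = {c.vessel_label for c in clips}
    if len(vessels) != 1:
        raise ValueError(f"clips must share one vessel label, got {sorted(vessels)}")
    patients = {c.patient_id for c in clips}
    known = split.train_patients | split.val_patients | split.test_patients
    if not patients <= known:
        raise ValueError("split does not cover all patients present")
    # leakage guard: train/test patient sets must not intersect
    assert not (split.train_patients & split.test_patients)

    tr_f, tr_w, tr_m = collect_partition(clips, split, "train")
    va_f, va_w, va_m = collect_partition(clips, split, "val")
    if len(tr_f) == 0:
        raise ValueError("empty train partition")

    model = build_model(mc)
    opt = Adam(model.params(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    best = (-1.0, None)
    history = []
    for epoch in range(tc.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(tr_f))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            prob = model.forward(tr_f[idx], tr_w[idx], train=True)
            loss, grad = _loss_and_logit_grad(prob, tr_m[idx], tc.loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            ep_loss += loss
            n_batches += 1
        row = {"epoch": epoch, "train_loss": ep_loss / max(n_batches, 1)}
        if len(va_f):
            vp = _forward_batched(model, va_f, va_w, tc.batch_size)
            row["val_dice"] = _batch_dice(vp, va_m)
            row["val_loss"] = compute_loss(vp[..., 0], va_m[..., 0], tc.loss)
            if row["val_dice"] > best[0]:
                best = (row["val_dice"], {k: v.copy()
                                          for k, v in model.state_dict().items()})
        row["seconds"] = time.perf_counter() - t0
        history.append(row)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, pd.DataFrame(history)
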
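"""Seeded intraoperative-ultrasound phantom generator.

Emulates the statistics of IOUS vessel clips that matter for segmentation:
dark (anechoic) elliptical vessel cross-sections embedded in a bright
parenchyma rendered with multiplicative gamma speckle, optional wedge-shaped
acoustic shadows, slow inter-frame probe drift, and three classes of
degenerate frames that occur in real recordings (near-black frames from
probe lift-off, frames without any target vessel, and motion-blurred
frames). Every frame carries its ground-truth mask, its defect label and an
*ideal* weight map (a smoothed copy of the true mask) so that downstream
modules have a fully labelled, download-free test surface.

This is a texture-level simulator, not a wave-propagation model: speckle is
drawn as spatially correlated gamma noise rather than simulated from
scatterer physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "SyntheticClip",
    "generate_clip",
    "generate_dataset",
    "easy_preset",
    "hard_preset",
    "VESSEL_LABELS",
]

#: Hepatic vessel vocabulary: caval/hepatic veins and portal branches.
VESSEL_LABELS = ("IVC", "RHV", "MHV", "LHV", "MPV", "LPV", "RPV", "ARPV", "PRPV")

DEFECT_OK = "ok"
DEFECT_BLACK = "blackness"
DEFECT_NO_TARGET = "no_target"
DEFECT_BLURRY = "blurry"


@dataclass
class PhantomConfig:
    """Rendering parameters for one synthetic clip.

    Intensities are on the [0, 1] grayscale; the defaults give the strong
    lumen/parenchyma contrast of a well-coupled probe. ``speckle_shape`` is
    the gamma shape of the multiplicative noise (mean fixed at 1); smaller
    values give harsher speckle. Probabilities are per frame (defects) or
    per clip (shadow); ``drift_px_per_frame`` translates every vessel along
    a fixed per-clip direction, emulating slow probe motion.
    """

    image_side: int = 256
    n_vessels: int = 2
    # hepatic vessel cross-sections span a sizable part of the field of view
    # (an IVC lumen of ~2 cm in a 6-8 cm deep view): radii as fraction of side
    vessel_radius_range: tuple[float, float] = (0.08, 0.16)
    lumen_intensity: float = 0.08
    background_intensity: float = 0.55
    speckle_shape: float = 4.0
    speckle_sigma: float = 0.7  # blur of the noise field, px
    shadow_probability: float = 0.0
    shadow_attenuation: float = 0.4
    blur_probability: float = 0.0
    blur_sigma: float = 8.0
    black_frame_probability: float = 0.0
    empty_frame_probability: float = 0.0
    drift_px_per_frame: float = 0.5
    frames_per_clip: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.lumen_intensity >= self.background_intensity:
            raise ValueError("lumen must be darker than background")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        for name in ("shadow_probability", "blur_probability",
                     "black_frame_probability", "empty_frame_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.vessel_radius_range[1] * self.image_side * 2 >= self.image_side:
            raise ValueError("vessel radius exceeds image side")


def easy_preset(**overrides) -> PhantomConfig:
    """High contrast, no shadows or defect frames: the training surface."""
    cfg = dict(shadow_probability=0.0, blur_probability=0.0,
               black_frame_probability=0.0, empty_frame_probability=0.0,
               drift_px_per_frame=0.5, speckle_shape=6.0)
    cfg.update(overrides)
    return PhantomConfig(**cfg)


def hard_preset(**overrides) -> PhantomConfig:
    """Shadows, faster drift and injected defect frames: the robustness surface."""
    cfg = dict(shadow_probability=0.3, blur_probability=0.10,
               black_frame_probability=0.08, empty_frame_probability=0.10,
               drift_px_per_frame=2.0, speckle_shape=4.0)
    cfg.update(overrides)
    return PhantomConfig(**cfg)


@dataclass
class SyntheticClip:
    """One rendered clip with full ground truth."""

    patient_id: str
    vessel_label: str
    clip_id: str
    frames: list  # float32 (S, S) in [0, 1]
    masks: list  # uint8 (S, S) in {0, 1}
    weight_maps: list  # float32 (S, S) in [0, 1]
    defect_labels: list  # str per frame

    def __len__(self):
        return len(self.frames)


def _ellipse_mask(side: int, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * x + s * y) / rx
    v = (-s * x + c * y) / ry
    return (u * u + v * v) <= 1.0


def _speckle(side: int, shape: float, sigma: float, rng) -> np.ndarray:
    field_ = rng.gamma(shape, 1.0 / shape, size=(side, side))
    if sigma > 0:
        field_ = gaussian_filter(field_, sigma)
    return field_.astype(np.float32)


def _shadow_field(side: int, attenuation: float, rng) -> np.ndarray:
    """Dark wedge fanning down from a random apex on the top edge."""
    apex_x = rng.uniform(0.2, 0.8) * side
    centre = rng.uniform(-0.3, 0.3)
    half_w = rng.uniform(0.08, 0.2)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    ang = np.arctan2(xx - apex_x, yy + 0.05 * side)
    inside = np.abs(ang - centre) < half_w
    f = np.ones((side, side))
    f[inside] = attenuation
    return gaussian_filter(f, 3.0).astype(np.float32)


def generate_clip(
    config: PhantomConfig,
    patient_id: str = "p000",
    vessel_label: str = "IVC",
    clip_id: str = "c000",
    seed: int | None = None,
) -> SyntheticClip:
    """Render one clip; fully deterministic given config and seed."""
    side = config.image_side
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_frames = config.frames_per_clip
    total_drift = config.drift_px_per_frame * (n_frames - 1)
    rmin, rmax = (r * side for r in config.vessel_radius_range)
    margin = rmax + total_drift / 2 + 2
    vessels = []
    for _ in range(config.n_vessels):
        vessels.append(dict(
            cy=rng.uniform(margin, side - margin),
            cx=rng.uniform(margin, side - margin),
            ry=rng.uniform(rmin, rmax),
            rx=rng.uniform(rmin, rmax),
            theta=rng.uniform(0, np.pi),
        ))
    phi = rng.uniform(0, 2 * np.pi)
    drift = np.array([np.cos(phi), np.sin(phi)]) * config.drift_px_per_frame
    # start centred so the drifted track stays inside the margin
    offset0 = -drift * (n_frames - 1) / 2.0

    shadow = None
    if rng.random() < config.shadow_probability:
        shadow = _shadow_field(side, config.shadow_attenuation, rng)

    frames, masks, wmaps, labels = [], [], [], []
    for t in range(n_frames):
        u = rng.random()
        p_black = config.black_frame_probability
        p_empty = config.empty_frame_probability
        p_blur = config.blur_probability
        if u < p_black:
            defect = DEFECT_BLACK
        elif u < p_black + p_empty:
            defect = DEFECT_NO_TARGET
        elif u < p_black + p_empty + p_blur:
            defect = DEFECT_BLURRY
        else:
            defect = DEFECT_OK

        off = offset0 + drift * t
        mask = np.zeros((side, side), dtype=bool)
        if defect not in (DEFECT_BLACK, DEFECT_NO_TARGET):
            for v in vessels:
                mask |= _ellipse_mask(side, v["cy"] + off[0], v["cx"] + off[1],
                                      v["ry"], v["rx"], v["theta"])

        if defect == DEFECT_BLACK:
            frame = (rng.random((side, side)) * 0.015).astype(np.float32)
        else:
            soft = gaussian_filter(mask.astype(np.float32), 1.0)
            clean = (config.background_intensity * (1.0 - soft)
                     + config.lumen_intensity * soft)
            frame = clean * _speckle(side, config.speckle_shape,
                                     config.speckle_sigma, rng)
            if shadow is not None:
                frame = frame * shadow
            if defect == DEFECT_BLURRY:
                frame = gaussian_filter(frame, config.blur_sigma)
            frame = np.clip(frame, 0.0, 1.0).astype(np.float32)

        mask8 = mask.astype(np.uint8)
        wmap = gaussian_filter(mask.astype(np.float32), 4.0)
        peak = wmap.max()
        if peak > 0:
            wmap = (wmap / peak).astype(np.float32)

        frames.append(frame)
        masks.append(mask8)
        wmaps.append(wmap.astype(np.float32))
        labels.append(defect)

    return SyntheticClip(patient_id, vessel_label, clip_id,
                         frames, masks, wmaps, labels)


def generate_dataset(
    out_dir,
    n_patients: int,
    clips_per_patient: int,
    config: PhantomConfig,
    vessel_labels: tuple[str, ...] = VESSEL_LABELS,
    master_seed: int | None = None,
) -> dict:
    """Write a phantom corpus in the on-disk clip layout and return the manifest.

    Layout: ``<out>/<patient>/<vessel>/<clip>/frame_%05d.png`` with parallel
    ``mask_%05d.png`` (0/255) and ``wmap_%05d.png``. Per-patient sub-seeds
    are spawned from the master seed so patients are statistically
    independent and any patient can be regenerated in isolation.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients to build a 3-way split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if master_seed is None else master_seed
    ss = np.random.SeedSequence(seed)
    patient_seeds = ss.spawn(n_patients)

    manifest = {"seed": int(seed), "config": asdict(config), "patients": {},
                "files": []}
    for i in range(n_patients):
        pid = f"p{i:03d}"
        clip_seeds = patient_seeds[i].spawn(clips_per_patient)
        manifest["patients"][pid] = []
        for j in range(clips_per_patient):
            vessel = vessel_labels[(i + j) % len(vessel_labels)]
            cid = f"c{j:03d}"
            sub_seed = int(clip_seeds[j].generate_state(1, np.uint32)[0])
            clip = generate_clip(config, pid, vessel, cid, seed=sub_seed)
            clip_dir = out_dir / pid / vessel / cid
            clip_dir.mkdir(parents=True, exist_ok=True)
            for t in range(len(clip)):
                f8 = np.round(clip.frames[t] * 255).astype(np.uint8)
                m8 = (clip.masks[t] * 255).astype(np.uint8)
                w8 = np.round(clip.weight_maps[t] * 255).astype(np.uint8)
                iio.imwrite(clip_dir / f"frame_{t:05d}.png", f8)
                iio.imwrite(clip_dir / f"mask_{t:05d}.png", m8)
                iio.imwrite(clip_dir / f"wmap_{t:05d}.png", w8)
                manifest["files"].append({
                    "patient_id": pid, "vessel": vessel, "clip_id": cid,
                    "frame_index": t,
                    "frame": str(clip_dir / f"frame_{t:05d}.png"),
                    "defect": clip.defect_labels[t],
                })
            manifest["patients"][pid].append({"vessel": vessel, "clip_id": cid,
                                              "n_frames": len(clip)})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
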
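"""2D-weighted attention-enriched U-Net.

The network is a five-stage encoder--decoder for binary vessel segmentation
in ultrasound frames. Its distinguishing element is the *weighted block*: at
each of the four encoder levels, a max-pooled pyramid level ``w_l`` of a
precomputed per-pixel saliency prior (the *weight map*) is fused with the
learned feature map ``LFM_l``. The fusion lifts ``w_l`` to 128 channels with
a 1x1 convolution, adds it to a 128-channel projection of the features,
refines the sum with 3x3 and 1x1 convolutions, and squashes the result to a
single-channel sigmoid gate ``X`` in [0, 1]. The gated skip passed to the
decoder is the element-wise product ``O_l = X * Q_l`` of the gate with the
max-pooled 128-channel features ``Q_l``.

The model consumes the frame and its weight map together; there is no
map-free mode, mirroring the intended use where the saliency prior is
available at both training and inference time.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = ["ModelConfig", "WeightedBlock", "WeightedUNet", "build_model"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_filters`` are the per-stage channel counts of the contracting
    path; the deliberately small widths keep single-frame inference fast
    enough for intraoperative use. ``attention_channels`` is the common
    width to which features and weight map are lifted inside each weighted
    block. ``dropout_rate`` defaults to zero (no dropout), matching the
    training regime the network was designed for.
    """

    input_side: int = 256
    encoder_filters: tuple[int, ...] = (32, 32, 64, 64, 128)
    kernel_size: int = 3
    attention_channels: int = 128
    dropout_rate: float = 0.0
    output_channels: int = 1
    decoder_filters: tuple[int, ...] = (64, 64, 32, 32)
    head_filters: int = 16
    seed: int = 0

    def __post_init__(self):
        self.encoder_filters = tuple(self.encoder_filters)
        self.decoder_filters = tuple(self.decoder_filters)
        if len(self.encoder_filters) != 5:
            raise ValueError("encoder_filters must have length 5")
        if len(self.decoder_filters) != 4:
            raise ValueError("decoder_filters must have length 4")
        if self.input_side % 16 != 0 or self.input_side < 16:
            raise ValueError("input_side must be a positive multiple of 16")
        if self.output_channels != 1:
            raise ValueError("the network is binary: output_channels must be 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class WeightedBlock:
    """Saliency-gated attention unit at encoder level ``l`` (1-based).

    Inputs: ``LFM_l`` with ``z_l`` channels at side ``S / 2**(l-1)`` and the
    pyramid level ``w_l`` at side ``S / 2**l``. Output: the gated skip
    ``O_l`` (``attention_channels`` channels, side ``S / 2**l``) and the
    gate ``X`` itself.
    """

    def __init__(self, z_l: int, channels: int, rng: np.random.Generator):
        self.proj = nn.Conv2d(z_l, channels, 1, rng)
        self.pool = nn.MaxPool2()
        self.lift = nn.Conv2d(1, channels, 1, rng)
        self.lift_relu = nn.ReLU()
        self.refine3 = nn.Conv2d(channels, channels, 3, rng)
        self.refine_relu = nn.ReLU()
        self.gate1 = nn.Conv2d(channels, 1, 1, rng)
        self.gate_sig = nn.Sigmoid()
        self._q: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self.last_gate: np.ndarray | None = None

    def layers(self):
        return [self.proj, self.lift, self.refine3, self.gate1]

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, lfm: np.ndarray, w_l: np.ndarray) -> np.ndarray:
        q = self.pool.forward(self.proj.forward(lfm))
        if w_l.shape[1:3] != q.shape[1:3]:
            raise ValueError(
                f"weight-map level side {w_l.shape[1:3]} does not match "
                f"pooled feature side {q.shape[1:3]}"
            )
        a = self.lift_relu.forward(self.lift.forward(w_l))
        o_int = q + a
        r = self.refine_relu.forward(self.refine3.forward(o_int))
        x = self.gate_sig.forward(self.gate1.forward(r))
        self._q, self._x = q, x
        self.last_gate = x
        return x * q

    def backward(self, g_o: np.ndarray) -> np.ndarray:
        q, x = self._q, self._x
        g_x = (g_o * q).sum(axis=-1, keepdims=True)
        g_q = g_o * x
        g_r = self.refine_relu.backward(self.gate1.backward(self.gate_sig.backward(g_x)))
        g_oint = self.refine3.backward(g_r)
        g_q = g_q + g_oint  # addition branch rejoins the feature pathway
        # lift branch: accumulate its parameter gradients, then stop — the
        # weight-map input itself is not trained
        self.lift.backward(self.lift_relu.backward(g_oint))
        return self.proj.backward(self.pool.backward(g_q))


class WeightedUNet:
    """The full encoder--decoder with weighted blocks on levels 1-4.

    Forward takes NHWC float32 batches: frames ``(N, S, S, 1)`` and weight
    maps of the same shape, both valued in [0, 1]. The weight-map pyramid is
    built internally by repeated 2x2 max pooling. Returns the per-pixel
    vessel probability map ``(N, S, S, 1)``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.encoder_filters
        ac = config.attention_channels
        self.enc = [
            nn.Conv2d(1 if i == 0 else f[i - 1], f[i], config.kernel_size, rng)
            for i in range(5)
        ]
        self.enc_relu = [nn.ReLU() for _ in range(5)]
        self.enc_pool = [nn.MaxPool2() for _ in range(4)]
        self.enc_drop = [nn.Dropout(config.dropout_rate, rng) for _ in range(5)]
        self.blocks = [WeightedBlock(f[i], ac, rng) for i in range(4)]
        d = config.decoder_filters
        # decoder block l consumes upsampled features concatenated with O_l
        dec_in = [f[4] + ac, d[0] + ac, d[1] + ac, d[2] + ac]
        self.dec = [nn.Conv2d(dec_in[i], d[i], config.kernel_size, rng) for i in range(4)]
        self.dec_relu = [nn.ReLU() for _ in range(4)]
        self.dec_up = [nn.Upsample2() for _ in range(4)]
        self.final = nn.Conv2d(d[3], config.head_filters, config.kernel_size, rng)
        self.final_relu = nn.ReLU()
        self.head = nn.Conv2d(config.head_filters, config.output_channels, 1, rng)
        self.head_sig = nn.Sigmoid()
        self._dec_split: list[int] = []
        self.last_prob: np.ndarray | None = None

    # ------------------------------------------------------------------ api

    def layers(self):
        convs = list(self.enc) + list(self.dec) + [self.final, self.head]
        for b in self.blocks:
            convs.extend(b.layers())
        return convs

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def weight_pyramid(self, wmap: np.ndarray) -> list[np.ndarray]:
        """Levels w_1..w_4 at sides S/2 .. S/16 via 2x2 max pooling."""
        levels = []
        w = wmap
        for _ in range(4):
            w = nn.maxpool2(w)
            levels.append(w)
        return levels

    def forward(
        self, frames: np.ndarray, wmaps: np.ndarray, train: bool = False
    ) -> np.ndarray:
        frames = self._check_input(frames, "frames")
        wmaps = self._check_input(wmaps, "weight maps")
        if frames.shape != wmaps.shape:
            raise ValueError("frames and weight maps must share one shape")
        pyramid = self.weight_pyramid(wmaps)
        x = frames
        skips = []
        for i in range(5):
            x = self.enc_relu[i].forward(self.enc[i].forward(x))
            x = self.enc_drop[i].forward(x, train=train)
            if i < 4:
                skips.append(self.blocks[i].forward(x, pyramid[i]))
                x = self.enc_pool[i].forward(x)
        self._dec_split = []
        for i in range(4):
            o_l = skips[3 - i]
            self._dec_split.append(x.shape[-1])
            x = np.concatenate([x, o_l], axis=-1)
            x = self.dec_relu[i].forward(self.dec[i].forward(x))
            x = self.dec_up[i].forward(x)
        x = self.final_relu.forward(self.final.forward(x))
        logits = self.head.forward(x)
        prob = self.head_sig.forward(logits)
        self.last_prob = prob
        return prob

    def backward(self, g_logits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits."""
        g = self.final_relu.backward(self.head.backward(g_logits))
        g = self.final.backward(g)
        g_skips = []
        for i in range(3, -1, -1):
            g = self.dec_up[i].backward(g)
            g = self.dec[i].backward(self.dec_relu[i].backward(g))
            n_up = self._dec_split[i]
            g, g_o = g[..., :n_up], g[..., n_up:]
            g_skips.append(g_o)
        g_skips = g_skips[::-1]  # now indexed by decoder step: level 4..1
        for i in range(4, -1, -1):
            if i < 4:
                g = self.enc_pool[i].backward(g)
                g = g + self.blocks[i].backward(g_skips[3 - i])
            g = self.enc_drop[i].backward(g)
            g = self.enc[i].backward(self.enc_relu[i].backward(g))

    def predict(
        self, frame: np.ndarray, wmap: np.ndarray, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """Segment one frame (or a batch). Returns (mask, probability map).

        The mask is ``probability >= threshold`` as uint8; inference is
        deterministic (no dropout, no randomness).
        """
        if wmap is None:
            raise ValueError("a weight map is required: the model has no map-free mode")
        single = frame.ndim == 2
        if single:
            frame = frame[None, ..., None]
            wmap = wmap[None, ..., None]
        prob = self.forward(
            np.asarray(frame, dtype=np.float32),
            np.asarray(wmap, dtype=np.float32),
            train=False,
        )
        mask = (prob >= threshold).astype(np.uint8)
        if single:
            return mask[0, ..., 0], prob[0, ..., 0]
        return mask, prob

    # ----------------------------------------------------------- persistence

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            src = state[f"p{i}"]
            if src.shape != p.value.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.value[...] = src

    def save(self, path) -> None:
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "WeightedUNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(ModelConfig(**cfg))
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model

    # -------------------------------------------------------------- internal

    def _check_input(self, x: np.ndarray, name: str) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError(f"{name} must be NHWC with one channel, got {x.shape}")
        s = self.config.input_side
        if x.shape[1] != s or x.shape[2] != s:
            raise ValueError(f"{name} must be {s}x{s}, got {x.shape[1]}x{x.shape[2]}")
        return x


def build_model(config: ModelConfig | None = None) -> WeightedUNet:
    """Construct a seeded, He-uniform-initialised weighted U-Net."""
    return WeightedUNet(config or ModelConfig())
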
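import numpy as np
import pytest

from iousseg.model import ModelConfig, build_model
from iousseg.phantom import easy_preset, generate_clip


@pytest.fixture(scope="session")
def tiny_model():
    """A structurally complete but very small network (16 px, few filters)."""
    cfg = ModelConfig(input_side=16, encoder_filters=(2, 2, 3, 3, 4),
                      decoder_filters=(3, 3, 2, 2), head_filters=2,
                      attention_channels=5, seed=1)
    return build_model(cfg)


@pytest.fixture(scope="session")
def easy_clip_64():
    """One defect-free high-contrast phantom clip at 64 px."""
    cfg = easy_preset(image_side=64, frames_per_clip=16, n_vessels=2, seed=3)
    return generate_clip(cfg, seed=11)


def batch_from_clip(clip):
    f = np.stack(clip.frames)[..., None].astype(np.float32)
    w = np.stack(clip.weight_maps)[..., None].astype(np.float32)
    m = np.stack(clip.masks)[..., None].astype(np.float32)
    return f, w, m
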
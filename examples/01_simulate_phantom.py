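"""Render one synthetic intraoperative-ultrasound clip and inspect it.

The phantom places dark (anechoic) vessel cross-sections in multiplicative
gamma speckle, drifts them between frames like a slowly moving probe, and
can inject the three degenerate-frame classes seen in real recordings.
"""

import numpy as np

from iousseg import hard_preset, generate_clip

cfg = hard_preset(image_side=128, frames_per_clip=10, seed=7)
clip = generate_clip(cfg, patient_id="p000", vessel_label="IVC", seed=7)

print(f"clip of {len(clip)} frames, vessel {clip.vessel_label}")
for t, (frame, mask, label) in enumerate(zip(clip.frames, clip.masks,
                                             clip.defect_labels)):
    inside = frame[mask == 1].mean() if mask.sum() else float("nan")
    outside = frame[mask == 0].mean()
    print(f"frame {t}: defect={label:9s} mean={frame.mean():.3f} "
          f"lumen={inside:.3f} parenchyma={outside:.3f} "
          f"vessel_area={mask.mean():.3f}")

# On clean frames the lumen should read much darker than the parenchyma
# (anechoic blood vs speckled liver tissue), and vessel_area is the
# ground-truth foreground fraction the segmentation model must recover.
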
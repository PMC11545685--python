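"""Train a small vessel model on phantoms and score held-out patients.

Follows the standard recipe (Adam, lr 1e-3, batch 16, no augmentation) at a
desk-scale problem size: 6 phantom patients at 48x48, a few epochs. Expect
a held-out Dice well above chance but below a fully converged run.
"""

import numpy as np

from iousseg import (ModelConfig, TrainConfig, aggregate, easy_preset,
                     evaluate_frame, generate_dataset, load_raw_dataset,
                     make_patient_split, train_vessel_model)
from iousseg.train import collect_partition
import tempfile
from pathlib import Path

with tempfile.TemporaryDirectory() as tmp:
    cfg = easy_preset(image_side=48, frames_per_clip=12, seed=0)
    generate_dataset(Path(tmp) / "d", 8, 1, cfg, vessel_labels=("IVC",))
    clips, report = load_raw_dataset(Path(tmp) / "d", side=48)

split = make_patient_split(sorted({c.patient_id for c in clips}), seed=0)
model, history = train_vessel_model(
    clips, split,
    ModelConfig(input_side=48, seed=0),
    TrainConfig(epochs=10, seed=0))
print(history[["epoch", "train_loss", "val_dice"]].to_string(index=False))

te_f, te_w, te_m = collect_partition(clips, split, "test")
records = []
for i in range(len(te_f)):
    prob = model.forward(te_f[i:i + 1], te_w[i:i + 1])
    records.append(evaluate_frame(prob[0, ..., 0],
                                  te_m[i, ..., 0].astype(np.uint8),
                                  vessel="IVC"))
print(aggregate(records).to_string(index=False))
# dice_mean is the headline number: pixel overlap between predicted and
# true vessel masks on patients the model never saw during training.
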
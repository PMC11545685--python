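"""End-to-end phantom pipeline: simulate -> preprocess -> train -> evaluate.

Used by the command-line ``end2end`` subcommand and by scripted
experiments. Every stage draws its randomness from sub-seeds spawned from
one master seed, so a run is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as m
from .model import ModelConfig
from .phantom import PhantomConfig, easy_preset, hard_preset, generate_dataset
from .preprocess import (QualityThresholds, load_raw_dataset,
                         make_patient_split, quality_report)
from .train import TrainConfig, collect_partition, train_vessel_model

__all__ = ["run_end_to_end"]


def _preset_config(preset: str, side: int, frames_per_clip: int,
                   seed: int) -> PhantomConfig:
    make = {"easy": easy_preset, "hard": hard_preset}[preset]
    return make(image_side=side, frames_per_clip=frames_per_clip, seed=seed)


def run_end_to_end(
    out_dir,
    seed: int = 0,
    preset: str = "easy",
    side: int = 64,
    n_patients: int = 8,
    clips_per_patient: int = 2,
    frames_per_clip: int = 8,
    epochs: int = 4,
    vessel: str = "IVC",
    mconfig: ModelConfig | None = None,
    tconfig: TrainConfig | None = None,
    thresholds: QualityThresholds | None = None,
) -> pd.DataFrame:
    """Run the full chain on a phantom corpus; returns the metrics table.

    Writes into ``out_dir``: the simulated corpus, the quality report, the
    patient split manifest, the per-epoch training history, the trained
    checkpoint, a run log and ``metrics.csv`` (per-vessel mean ± SD over
    held-out test frames).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    t_start = time.time()

    def log(msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with open(log_path, "a") as fh:
            fh.write(f"[{stamp}] (+{time.time() - t_start:7.1f}s) {msg}\n")

    ss = np.random.SeedSequence(seed)
    sim_seed, split_seed, train_seed, model_seed = (
        int(s.generate_state(1, np.uint32)[0]) % (2**31) for s in ss.spawn(4))

    pconfig = _preset_config(preset, side, frames_per_clip, sim_seed)
    log(f"seed={seed} preset={preset} side={side} patients={n_patients}")
    generate_dataset(out_dir / "data", n_patients, clips_per_patient,
                     pconfig, vessel_labels=(vessel,))
    log("simulated corpus written")

    clips, report = load_raw_dataset(out_dir / "data", side=side,
                                     thresholds=thresholds)
    quality_report(report, out_dir / "quality_report.csv")
    patients = sorted({c.patient_id for c in clips})
    split = make_patient_split(patients, seed=split_seed)
    split.to_json(out_dir / "split.json")
    log(f"{len(clips)} clips kept; split "
        f"{len(split.train_patients)}/{len(split.val_patients)}/{len(split.test_patients)}")

    mc = mconfig or ModelConfig(input_side=side, seed=model_seed)
    tc = tconfig or TrainConfig(epochs=epochs, seed=train_seed)
    model, history = train_vessel_model(clips, split, mc, tc)
    history.to_csv(out_dir / "history.csv", index=False)
    model.save(out_dir / "model.npz")
    log(f"training done: {len(history)} epochs")

    te_f, te_w, te_m = collect_partition(clips, split, "test")
    records = []
    for i in range(0, len(te_f), tc.batch_size):
        prob = model.forward(te_f[i:i + tc.batch_size],
                             te_w[i:i + tc.batch_size], train=False)
        for j in range(len(prob)):
            records.append(m.evaluate_frame(prob[j, ..., 0],
                                            te_m[i + j, ..., 0].astype(np.uint8),
                                            vessel=vessel))
    table = m.aggregate(records)
    table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
    meta = {"seed": seed, "preset": preset, "side": side,
            "n_patients": n_patients, "clips_per_patient": clips_per_patient,
            "frames_per_clip": frames_per_clip, "epochs": epochs,
            "vessel": vessel,
            "model": dataclasses.asdict(mc), "train": dataclasses.asdict(tc)}
    (out_dir / "run_config.json").write_text(json.dumps(meta, indent=1))
    log("metrics.csv written")
    return table
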
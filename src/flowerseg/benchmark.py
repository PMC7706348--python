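"""Desk-scale end-to-end benchmark: train on synthetic scenes, score all
three masks (binarization, CNN, combined) against generated ground truth.

Problem sizes here are the package's standard desk-scale protocol: 256x256
scenes, a dozen flower scenes plus four flower-free scenes for training,
and sliding-window stride 4 at evaluation.  The training seed, scene seeds
and sampling seeds all derive from one benchmark seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cnn import NetConfig, Network, TrainConfig, train
from .metrics import evaluate_bundle
from .pipeline import run_pipeline
from .synthgen import SceneSpec, generate_benchmark, scene_to_trainset

__all__ = ["train_default_network", "run_benchmark", "median_scores"]

#: offsets carving independent seed ranges out of one benchmark seed
_TRAIN_SCENES_OFF = 10_000
_BG_SCENES_OFF = 20_000
_EVAL_SCENES_OFF = 30_000


def train_default_network(
    seed: int,
    n_train_scenes: int = 12,
    n_background_scenes: int = 4,
    n_neg_per_image: int = 60,
    max_steps: int = 30,
    spec: SceneSpec | None = None,
):
    """Train the default small network on synthetic patches.

    Positives come from ``n_train_scenes`` flower scenes (one patch per
    planted flower), negatives from flower-free scenes that still contain
    distractors — the classifier must learn that a bright speck without
    flower-scale extent is background.  Returns (network, record, manifest).
    """
    spec = spec or SceneSpec()
    flower_scenes, _ = generate_benchmark(spec, n_train_scenes, seed + _TRAIN_SCENES_OFF)
    bg_spec = replace(spec, n_flowers=0)
    bg_scenes, _ = generate_benchmark(bg_spec, n_background_scenes, seed + _BG_SCENES_OFF)
    manifest = scene_to_trainset(
        flower_scenes, bg_scenes, n_neg_per_image=n_neg_per_image, seed=seed
    )
    network = Network.initialize(NetConfig(), seed=seed)
    network, record = train(
        network, manifest, TrainConfig(seed=seed, max_steps=max_steps)
    )
    return network, record, manifest


def run_benchmark(
    network,
    seed: int,
    n_scenes: int = 20,
    stride: int = 4,
    spec: SceneSpec | None = None,
) -> pd.DataFrame:
    """Per-scene metrics of bin/cnn/combined masks on fresh seeded scenes."""
    spec = spec or SceneSpec()
    scenes, _ = generate_benchmark(spec, n_scenes, seed + _EVAL_SCENES_OFF)
    rows = []
    for sc in scenes:
        bundle = run_pipeline(network, sc.image, stride=stride)
        reports = evaluate_bundle(bundle, sc.truth)
        for name, rep in reports.items():
            rows.append(
                {
                    "scene_seed": sc.spec.seed,
                    "illumination": sc.spec.illumination,
                    "mask": name,
                    "recall": rep.recall,
                    "precision": rep.precision,
                    "f1": rep.f1,
                    "iou": rep.iou,
                }
            )
    return pd.DataFrame(rows)


def median_scores(results: pd.DataFrame) -> pd.DataFrame:
    """Median of each metric per mask type."""
    return results.groupby("mask")[["recall", "precision", "f1", "iou"]].median()
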
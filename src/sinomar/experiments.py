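"""Desk-scale reference experiments.

This module pins down the study conditions used by the package's own
benchmark: a reproducible, CPU-sized version of the full pipeline
(simulate paired sinograms -> train the completion network -> score
held-out trace-region MAE against the linear-interpolation baseline).

The rig is deliberately small so a complete multi-seed comparison runs on a
single CPU core in minutes: 48-pixel ellipse phantoms with 1-2 metal discs,
64-detector x 64-angle parallel-beam sinograms, trace dilation 1, a
depth-4 / base-16 completion network, and 200 Adam steps at batch 8 over
100 training pairs with 10 held-out pairs.  All randomness derives from the
experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import GenerationConfig, sample_random_phantom
from .projection import ScanGeometry
from .traces import SinogramPair, make_pair
from .baselines import li_mar
from .evaluate import mae
from .network import (NetConfig, TrainConfig, train, validation_trace_mae)

__all__ = [
    "DESK_GENERATION",
    "desk_geometry",
    "desk_net_config",
    "desk_train_config",
    "generate_desk_pairs",
    "LearningResult",
    "run_learning_experiment",
]

DESK_GENERATION = GenerationConfig(
    image_size=48,
    metal_count_range=(1, 2),
    metal_radius_range=(0.06, 0.15),
    n_internal_range=(1, 3),
)

DESK_N_TRAIN = 100
DESK_N_HELDOUT = 10
DESK_DILATION_PX = 1


def desk_geometry() -> ScanGeometry:
    return ScanGeometry.uniform(n_detectors=64, n_angles=64)


def desk_net_config() -> NetConfig:
    return NetConfig.desk()


def desk_train_config(seed: int, **overrides) -> TrainConfig:
    cfg = dict(steps=200, batch_size=8, learning_rate=1e-3, seed=seed)
    cfg.update(overrides)
    return TrainConfig(**cfg)


def generate_desk_pairs(seed: int, n: int, offset: int = 0
                        ) -> list[SinogramPair]:
    """n simulation pairs; phantom seeds are derived from (seed, offset) so
    train and held-out sets never overlap."""
    geom = desk_geometry()
    return [
        make_pair(sample_random_phantom(seed * 100_000 + offset + i,
                                        DESK_GENERATION),
                  geom, dilation_px=DESK_DILATION_PX)
        for i in range(n)
    ]


@dataclass(frozen=True)
class LearningResult:
    """Held-out trace-region MAE of the trained network and the baselines."""

    seed: int
    net_trace_mae: float
    li_trace_mae: float
    zero_fill_trace_mae: float
    n_heldout_trace_pixels: int


def run_learning_experiment(seed: int, use_mask: bool = True,
                            use_amp: bool = True, use_diff: bool = True
                            ) -> LearningResult:
    """One full desk-scale run: simulate, train, and score on held-out pairs.

    The ablation flags select the training objective (full composite loss by
    default); evaluation is always trace-region MAE of the composited
    completion versus the label, alongside the linear-interpolation and
    zero-fill baselines on the same held-out pairs.
    """
    train_pairs = generate_desk_pairs(seed, DESK_N_TRAIN)
    heldout = generate_desk_pairs(seed, DESK_N_HELDOUT, offset=50_000)

    tc = desk_train_config(seed, use_mask=use_mask, use_amp=use_amp,
                           use_diff=use_diff)
    model, _ = train(train_pairs, desk_net_config(), tc)

    net = validation_trace_mae(model, heldout)
    li = float(np.mean([mae(li_mar(p.corrupted, p.mask), p.label,
                            region=p.mask) for p in heldout]))
    zero = float(np.mean([mae(p.corrupted, p.label, region=p.mask)
                          for p in heldout]))
    n_trace = int(sum(p.mask.values.sum() for p in heldout))
    return LearningResult(seed, net, li, zero, n_trace)
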
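"""Training objectives.

The total objective is a weighted sum of the instance-branch loss (the
conventional box + mask + classification triplet) and the part-segmentation
loss, a mean one-vs-rest binary cross-entropy between the predicted part
probabilities and the one-hot ground-truth part map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import N_PART_CLASSES

EPS = 1e-7


@dataclass
class LossConfig:
    """Weights balancing the instance and part objectives (both 1 by default)."""

    lambda_inst: float = 1.0
    lambda_part: float = 1.0

    def validate(self) -> None:
        if self.lambda_inst < 0 or self.lambda_part < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_inst == 0 and self.lambda_part == 0:
            raise ValueError("at least one loss weight must be positive")


def one_hot_parts(part_map: np.ndarray) -> np.ndarray:
    """One-vs-rest encoding of a {0..3} part-label map, shape (4, H, W)."""
    part_map = np.asarray(part_map)
    return np.stack([(part_map == c).astype(float) for c in range(N_PART_CLASSES)])


def part_loss(part_probs: np.ndarray, gt_part_map: np.ndarray,
              eps: float = EPS) -> float:
    """Mean binary cross-entropy over pixels and part channels.

    ``part_probs`` holds per-channel probabilities in (0, 1) (clipped at
    ``eps``); the ground truth is a part-label map, one-hot encoded
    internally.  A constant 0.5 prediction yields ln 2 regardless of the
    targets.
    """
    probs = np.clip(np.asarray(part_probs, dtype=float), eps, 1.0 - eps)
    if probs.ndim != 3 or probs.shape[0] != N_PART_CLASSES:
        raise ValueError(f"part probabilities must be ({N_PART_CLASSES}, H, W)")
    targets = one_hot_parts(gt_part_map)
    if targets.shape != probs.shape:
        raise ValueError("probability and target shapes differ")
    return float(-np.mean(targets * np.log(probs) + (1 - targets) * np.log(1 - probs)))


def instance_loss(l_bbox: float, l_mask: float, l_cls: float) -> float:
    """L_inst = L_bbox + L_mask + L_cls."""
    return float(l_bbox + l_mask + l_cls)


def total_loss(l_inst: float, l_part: float, cfg: LossConfig | None = None) -> float:
    """L_total = lambda_inst * L_inst + lambda_part * L_part."""
    cfg = cfg or LossConfig()
    cfg.validate()
    return float(cfg.lambda_inst * l_inst + cfg.lambda_part * l_part)
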
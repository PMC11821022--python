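"""Instance extraction and instance/part fusion.

The instance branch turns the network's whole-cell foreground probability
into discrete detections: the probability map is thresholded, connected
components become candidate instances, and each receives a bounding box, a
full-resolution binary mask and a confidence score (its mean foreground
probability).  The fusion step then restricts the global part logits to
each instance's support — pixels outside the instance mask stay background,
so a parsing's labelled support is always contained in its instance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import N_PART_CLASSES, NetConfig, PartParsingNet, ShapeError


@dataclass
class InstancePrediction:
    """One detection: half-open box (r0, c0, r1, c1), score, binary mask."""

    box: tuple[int, int, int, int]
    score: float
    mask: np.ndarray
    label: str = "sperm"

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r1 > r0 and c1 > c0):
            raise ValueError("degenerate bounding box")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class ParsingResult:
    """Fused per-instance parsing: part labels within the instance mask."""

    instance: InstancePrediction
    labels: np.ndarray  # S_final: part labels, 0 outside the instance

    @property
    def score(self) -> float:
        return self.instance.score

    @property
    def box(self) -> tuple[int, int, int, int]:
        return self.instance.box

    @property
    def part_masks(self) -> dict[int, np.ndarray]:
        return {p: self.labels == p for p in (1, 2, 3) if np.any(self.labels == p)}


def extract_instances(foreground_prob: np.ndarray,
                      mask_threshold: float = 0.5,
                      score_threshold: float = 0.5,
                      min_size_px: int = 10) -> list[InstancePrediction]:
    """Connected-component detections from a foreground probability map."""
    binary = foreground_prob >= mask_threshold
    labelled, n = ndimage.label(binary)
    out = []
    for i in range(1, n + 1):
        mask = labelled == i
        if mask.sum() < min_size_px:
            continue
        score = float(foreground_prob[mask].mean())
        if score < score_threshold:
            continue
        rows, cols = np.nonzero(mask)
        out.append(InstancePrediction(
            box=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
            score=score, mask=mask))
    out.sort(key=lambda p: -p.score)
    return out


def instance_branch(net: PartParsingNet, image: np.ndarray,
                    cfg: NetConfig | None = None) -> list[InstancePrediction]:
    """Run the network and extract score-sorted instance detections."""
    cfg = cfg or net.cfg
    prob = net.predict_foreground_prob(image)
    return extract_instances(prob, cfg.mask_threshold, cfg.score_threshold,
                             cfg.min_instance_px)


def align_and_fuse(instances: list[InstancePrediction],
                   part_logits: np.ndarray) -> list[ParsingResult]:
    """Fuse instance masks with the global part logits (S_final = S_inst * S_p).

    ``part_logits`` must already be at image resolution; the per-pixel part
    label is the channel argmax (ties resolved to the lowest class index by
    the argmax convention), kept only on the instance support.
    """
    part_logits = np.asarray(part_logits, dtype=float)
    if part_logits.ndim != 3 or part_logits.shape[0] != N_PART_CLASSES:
        raise ShapeError(f"part logits must be ({N_PART_CLASSES}, H, W)")
    labels_global = np.argmax(part_logits, axis=0)
    results = []
    for inst in instances:
        if inst.mask.shape != labels_global.shape:
            raise ShapeError(
                f"instance mask {inst.mask.shape} does not match part logits "
                f"resolution {labels_global.shape}")
        labels = np.where(inst.mask, labels_global, 0)
        results.append(ParsingResult(instance=inst, labels=labels))
    return results


def parse_image(net: PartParsingNet, image: np.ndarray,
                cfg: NetConfig | None = None) -> tuple[list[ParsingResult], np.ndarray]:
    """Full inference: detections fused with part logits, plus the part map."""
    cfg = cfg or net.cfg
    out = net.forward(image)
    prob = 1.0 / (1.0 + np.exp(-out["s_w_up"].data[0]))
    instances = extract_instances(prob, cfg.mask_threshold, cfg.score_threshold,
                                  cfg.min_instance_px)
    results = align_and_fuse(instances, out["s_p_up"].data)
    part_map = np.argmax(out["s_p_up"].data, axis=0)
    return results, part_map
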
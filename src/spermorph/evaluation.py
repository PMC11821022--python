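"""Part-parsing evaluation metrics.

Two families of metrics are provided, following the multi-human-parsing
evaluation protocol:

* **global**: per-class IoU of the semantic part map and its mean (mIoU);
* **instance-level**: predictions are greedily matched to ground-truth
  instances by descending confidence score, each prediction taking the
  unmatched ground-truth instance with the highest mean part IoU.  From the
  matches we compute average precision at a mean-part-IoU threshold
  (AP^p_50 at 0.5), its average over thresholds 0.1..0.9 (AP^p_vol), and
  the percentage of correctly parsed parts (PCP50: part IoU >= 0.5 among
  matched pairs, over all ground-truth parts).

All metrics are percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import PART_LABELS

AP_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))  # 0.1 .. 0.9


@dataclass
class GroundTruthParsing:
    """Ground truth as an instance-ID map plus a part-label map."""

    instance_map: np.ndarray
    part_map: np.ndarray

    def __post_init__(self) -> None:
        self.instance_map = np.asarray(self.instance_map)
        self.part_map = np.asarray(self.part_map)
        if self.instance_map.shape != self.part_map.shape:
            raise ValueError("instance and part maps must share a shape")
        if np.any((self.part_map > 0) != (self.instance_map > 0)):
            raise ValueError("instance and part maps must share their support")

    @property
    def instance_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.instance_map) if i != 0)

    def part_mask(self, instance_id: int, part: int) -> np.ndarray:
        return (self.instance_map == instance_id) & (self.part_map == part)

    def parts_present(self, instance_id: int) -> list[int]:
        inside = self.part_map[self.instance_map == instance_id]
        return [p for p in PART_LABELS if np.any(inside == p)]


@dataclass
class MetricReport:
    """The four headline parsing metrics (percent) plus the per-class table."""

    miou: float
    ap_vol: Optional[float]
    ap_50: Optional[float]
    pcp_50: Optional[float]
    per_class_iou: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mIoU": self.miou,
            "AP_vol": self.ap_vol,
            "AP_50": self.ap_50,
            "PCP_50": self.pcp_50,
            "per_class_IoU": {int(k): v for k, v in self.per_class_iou.items()},
        }


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    if union == 0:
        return float("nan")
    return np.count_nonzero(a & b) / union


def miou(pred_map: np.ndarray, gt_map: np.ndarray,
         include_background: bool = False) -> tuple[float, dict[int, float]]:
    """Mean IoU (percent) over classes present in prediction or ground truth.

    Background is excluded by default so that sparse scenes are not
    dominated by trivially correct background pixels.  Returns the mean and
    the per-class IoU table (percent).
    """
    pred_map = np.asarray(pred_map)
    gt_map = np.asarray(gt_map)
    if pred_map.shape != gt_map.shape:
        raise ValueError("prediction and ground truth shapes differ")
    classes = sorted(set(np.unique(pred_map)) | set(np.unique(gt_map)))
    if not include_background:
        classes = [c for c in classes if c != 0]
    table = {}
    for c in classes:
        v = _iou(pred_map == c, gt_map == c)
        if not np.isnan(v):
            table[int(c)] = 100.0 * v
    mean = float(np.mean(list(table.values()))) if table else 100.0
    return mean, table


# ---------------------------------------------------------------------------
# Instance-level metrics
# ---------------------------------------------------------------------------

@dataclass
class InstanceMatch:
    """One score-ranked prediction and its (possibly absent) GT assignment."""

    score: float
    gt_id: Optional[int]
    mean_part_iou: float
    part_ious: dict[int, float] = field(default_factory=dict)


def _mean_part_iou(pred_parts: dict[int, np.ndarray], gt: GroundTruthParsing,
                   gt_id: int) -> tuple[float, dict[int, float]]:
    """Mean IoU over the parts present in this GT instance."""
    parts = gt.parts_present(gt_id)
    ious = {}
    for p in parts:
        gmask = gt.part_mask(gt_id, p)
        pmask = pred_parts.get(p)
        ious[p] = 0.0 if pmask is None else _iou(pmask, gmask)
        if np.isnan(ious[p]):
            ious[p] = 0.0
    mean = float(np.mean(list(ious.values()))) if ious else 0.0
    return mean, ious


def match_instances(predictions: Sequence, gt: GroundTruthParsing) -> list[InstanceMatch]:
    """Greedy score-descending matching of predictions to GT instances.

    Each prediction is an object with a ``score`` and a ``part_masks``
    mapping (part label -> boolean mask), e.g. a ``ParsingResult`` instance.
    A prediction claims the still-unmatched GT instance of highest mean part
    IoU; duplicates of an already-claimed GT instance stay unmatched (false
    positives).
    """
    order = sorted(range(len(predictions)),
                   key=lambda i: -float(predictions[i].score))
    taken: set[int] = set()
    matches: list[InstanceMatch] = []
    for i in order:
        pred = predictions[i]
        best_id, best_iou, best_parts = None, 0.0, {}
        for gid in gt.instance_ids:
            if gid in taken:
                continue
            m, ious = _mean_part_iou(pred.part_masks, gt, gid)
            if m > best_iou:
                best_id, best_iou, best_parts = gid, m, ious
        if best_id is not None:
            taken.add(best_id)
        matches.append(InstanceMatch(score=float(pred.score), gt_id=best_id,
                                     mean_part_iou=best_iou, part_ious=best_parts))
    return matches


def ap_at(matches: Sequence[InstanceMatch], n_gt: int, threshold: float) -> Optional[float]:
    """Average precision (percent) at one mean-part-IoU threshold.

    The PR curve is built over score-ranked predictions (true positive iff
    matched with mean part IoU >= threshold); AP is the area under the
    all-point-interpolated curve.
    """
    if n_gt == 0:
        return None
    if not matches:
        return 0.0
    tp = np.array([m.gt_id is not None and m.mean_part_iou >= threshold
                   for m in matches], dtype=float)
    fp = 1.0 - tp
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(fp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # all-point interpolation: precision envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    ap = float(np.sum((r[1:] - r[:-1]) * prec_env))
    return 100.0 * ap


def ap_vol(matches: Sequence[InstanceMatch], n_gt: int) -> Optional[float]:
    """Mean AP over the nine thresholds 0.1, 0.2, ..., 0.9 (percent)."""
    vals = [ap_at(matches, n_gt, t) for t in AP_THRESHOLDS]
    if any(v is None for v in vals):
        return None
    return float(np.mean(vals))


def pcp50(matches: Sequence[InstanceMatch], gt: GroundTruthParsing,
          threshold: float = 0.5) -> Optional[float]:
    """Percentage of correctly parsed parts among matched instances.

    A part counts as correct iff its IoU >= threshold within a matched
    pair; the denominator is the number of parts present in the ground
    truth (over all GT instances, matched or not).
    """
    total = sum(len(gt.parts_present(gid)) for gid in gt.instance_ids)
    if total == 0:
        return None
    correct = 0
    for m in matches:
        if m.gt_id is None:
            continue
        correct += sum(1 for v in m.part_ious.values() if v >= threshold)
    return 100.0 * correct / total


def evaluate(predictions: Sequence, gt: GroundTruthParsing,
             pred_part_map: Optional[np.ndarray] = None,
             include_background: bool = False) -> MetricReport:
    """Full metric report for one scene (or pooled predictions).

    ``pred_part_map`` is the global semantic part map used for mIoU; when
    omitted it is assembled from the predictions' part masks (higher-score
    predictions painted last).
    """
    if pred_part_map is None:
        pred_part_map = np.zeros_like(gt.part_map)
        for pred in sorted(predictions, key=lambda p: float(p.score)):
            for part, mask in pred.part_masks.items():
                pred_part_map[mask] = part
    mean, table = miou(pred_part_map, gt.part_map, include_background)
    matches = match_instances(predictions, gt)
    n_gt = len(gt.instance_ids)
    return MetricReport(
        miou=mean,
        ap_vol=ap_vol(matches, n_gt),
        ap_50=ap_at(matches, n_gt, 0.5),
        pcp_50=pcp50(matches, gt),
        per_class_iou=table,
    )
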
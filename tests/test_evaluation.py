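"""Parsing metrics: mIoU, instance matching, AP sweep, PCP50."""

import numpy as np
import pytest

from spermorph.evaluation import (
    AP_THRESHOLDS,
    GroundTruthParsing,
    ap_at,
    ap_vol,
    evaluate,
    match_instances,
    miou,
    pcp50,
)
from spermorph.nn.instances import InstancePrediction, ParsingResult


def make_pred(mask_by_part, score, shape=(8, 8)):
    labels = np.zeros(shape, dtype=int)
    for part, mask in mask_by_part.items():
        labels[mask] = part
    support = labels > 0
    rows, cols = np.nonzero(support)
    inst = InstancePrediction((rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
                              score, support)
    return ParsingResult(inst, labels)


def two_instance_gt(shape=(8, 8)):
    inst = np.zeros(shape, dtype=int)
    part = np.zeros(shape, dtype=int)
    inst[1:4, 1:3], part[1:4, 1:3] = 1, 1  # instance 1: head only region
    inst[1:4, 3:5], part[1:4, 3:5] = 1, 3  # plus a tail region
    inst[5:7, 5:8], part[5:7, 5:8] = 2, 1
    return GroundTruthParsing(inst, part)


class TestMiou:
    def test_perfect_prediction_is_100(self):
        gt = np.array([[0, 1], [2, 3]])
        mean, table = miou(gt, gt)
        assert mean == 100.0
        assert all(v == 100.0 for v in table.values())

    def test_complement_prediction_is_zero(self):
        gt = np.array([[1, 1], [2, 2]])
        pred = np.array([[2, 2], [1, 1]])
        mean, _ = miou(pred, gt)
        assert mean == 0.0

    def test_hand_counted_half_overlap(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[:, :2] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[:, 1:3] = 1
        mean, table = miou(pred, gt)
        assert table[1] == pytest.approx(100 / 3)  # 4 / 12 px
        assert mean == pytest.approx(100 / 3)

    def test_background_included_on_request(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[0, 0] = 1
        mean_bg, table_bg = miou(gt, gt, include_background=True)
        assert 0 in table_bg and mean_bg == 100.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            miou(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMatching:
    def test_exact_prediction_matches_with_iou_one(self):
        gt = two_instance_gt()
        pred = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.9)
        matches = match_instances([pred], gt)
        assert matches[0].gt_id == 1
        assert matches[0].mean_part_iou == pytest.approx(1.0)

    def test_duplicate_prediction_is_false_positive(self):
        gt = two_instance_gt()
        pred = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.9)
        dup = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.8)
        matches = match_instances([pred, dup], gt)
        assert matches[0].gt_id == 1
        assert matches[1].gt_id in (None, 2)
        if matches[1].gt_id == 2:  # the duplicate may claim the other instance
            assert matches[1].mean_part_iou < 0.5

    def test_two_by_two_matches_brute_force_optimum(self):
        gt = two_instance_gt()
        p1 = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.95)
        p2 = make_pred({1: gt.part_mask(2, 1)}, 0.90)
        matches = match_instances([p1, p2], gt)
        got = {m.gt_id for m in matches}
        assert got == {1, 2}  # exhaustive assignment over the 2x2 case
        assert all(m.mean_part_iou == pytest.approx(1.0) for m in matches)


class TestAveragePrecision:
    def test_threshold_sweep_is_0p1_to_0p9(self):
        assert AP_THRESHOLDS == tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
        assert len(AP_THRESHOLDS) == 9

    def test_perfect_predictions_give_100_everywhere(self):
        gt = two_instance_gt()
        p1 = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.95)
        p2 = make_pred({1: gt.part_mask(2, 1)}, 0.90)
        matches = match_instances([p1, p2], gt)
        for t in AP_THRESHOLDS:
            assert ap_at(matches, 2, t) == 100.0
        assert ap_vol(matches, 2) == 100.0

    def test_hand_built_pr_curve_at_half(self):
        """3 score-ranked predictions with mean IoUs 0.95 / 0.55 / 0.2 vs 3 GTs."""
        from spermorph.evaluation import InstanceMatch
        matches = [InstanceMatch(0.9, 1, 0.95), InstanceMatch(0.8, 2, 0.55),
                   InstanceMatch(0.7, 3, 0.20)]
        # precision at ranks: 1, 1, 2/3 ; recall: 1/3, 2/3, 2/3
        # all-point AP = 1/3 * 1 + 1/3 * 1 = 2/3
        assert ap_at(matches, 3, 0.5) == pytest.approx(200.0 / 3)

    def test_no_gt_reports_absent(self):
        assert ap_at([], 0, 0.5) is None

    def test_ap_vol_bounded_by_most_permissive_threshold(self):
        from spermorph.evaluation import InstanceMatch
        matches = [InstanceMatch(0.9, 1, 0.45), InstanceMatch(0.8, None, 0.0)]
        assert ap_vol(matches, 2) <= ap_at(matches, 2, 0.1)


class TestPcp50:
    def test_perfect_parsing_is_100(self):
        gt = two_instance_gt()
        p1 = make_pred({1: gt.part_mask(1, 1), 3: gt.part_mask(1, 3)}, 0.95)
        p2 = make_pred({1: gt.part_mask(2, 1)}, 0.90)
        assert pcp50(match_instances([p1, p2], gt), gt) == 100.0

    def test_one_of_three_parts_correct(self):
        inst = np.zeros((9, 9), dtype=int)
        part = np.zeros((9, 9), dtype=int)
        inst[0:3, 0:3], part[0:3, 0:3] = 1, 1
        inst[4:6, 0:3], part[4:6, 0:3] = 1, 2
        inst[7:9, 0:3], part[7:9, 0:3] = 1, 3
        gt = GroundTruthParsing(inst, part)
        pred = make_pred({1: part == 1, 2: np.zeros_like(part, bool),
                          3: np.zeros_like(part, bool)}, 0.9, shape=(9, 9))
        score = pcp50(match_instances([pred], gt), gt)
        assert score == pytest.approx(100 / 3)

    def test_empty_prediction_set_scores_zero(self):
        gt = two_instance_gt()
        assert pcp50([], gt) == 0.0


class TestReportAndMonotonicity:
    def test_self_evaluation_is_100_on_all_metrics(self, tiny_scenes):
        scene = tiny_scenes[0]
        gt = GroundTruthParsing(scene.instance_map, scene.part_map)
        preds = []
        for gid in gt.instance_ids:
            sel = scene.instance_map == gid
            parts = {p: sel & (scene.part_map == p) for p in (1, 2, 3)}
            preds.append(make_pred({k: v for k, v in parts.items() if v.any()},
                                   1.0, shape=scene.part_map.shape))
        rep = evaluate(preds, gt)
        assert rep.miou == 100.0
        assert rep.ap_50 == 100.0
        assert rep.ap_vol == 100.0
        assert rep.pcp_50 == 100.0

    def test_corruption_never_raises_any_metric(self, tiny_scenes):
        scene = tiny_scenes[0]
        gt = GroundTruthParsing(scene.instance_map, scene.part_map)
        def preds_from(part_map):
            out = []
            for gid in gt.instance_ids:
                sel = scene.instance_map == gid
                parts = {p: sel & (part_map == p) for p in (1, 2, 3)}
                parts = {k: v for k, v in parts.items() if v.any()}
                if parts:
                    out.append(make_pred(parts, 1.0, shape=part_map.shape))
            return out
        perfect = evaluate(preds_from(scene.part_map), gt,
                           pred_part_map=scene.part_map)
        corrupted_map = scene.part_map.copy()
        corrupted_map[corrupted_map == 3] = 2  # destroy every tail
        corrupted = evaluate(preds_from(corrupted_map), gt,
                             pred_part_map=corrupted_map)
        for key in ("mIoU", "AP_vol", "AP_50", "PCP_50"):
            assert corrupted.as_dict()[key] <= perfect.as_dict()[key]
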
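"""Parsing network: algebraic stage contracts, losses, training mechanics."""

import numpy as np
import pytest

from spermorph import nn
from spermorph.nn import autograd as ag
from spermorph.nn.model import FeatureMap, ShapeError, fuse_pyramid, part_phase, whole_phase


def _pyramid(c=1, base=8, fill=0.0):
    levels = []
    for i, stride in enumerate((4, 8, 16, 32)):
        size = base // (2**i)
        levels.append(FeatureMap(np.full((c, size, size), fill), stride))
    return levels


class TestFusePyramid:
    def test_zero_pyramid_zero_weights_gives_zero(self):
        w = np.zeros((1, 4, 1, 1))
        fused = fuse_pyramid(_pyramid(), w)
        assert np.allclose(fused.data, 0.0)

    def test_output_at_p2_resolution(self):
        levels = [FeatureMap(np.zeros((2, 64, 64)), 4),
                  FeatureMap(np.zeros((2, 32, 32)), 8),
                  FeatureMap(np.zeros((2, 16, 16)), 16),
                  FeatureMap(np.zeros((2, 8, 8)), 32)]
        fused = fuse_pyramid(levels, np.zeros((2, 8, 1, 1)))
        assert fused.data.shape[1:] == (64, 64)
        assert fused.stride == 4

    def test_channel_mismatch_names_offending_level(self):
        levels = _pyramid()
        levels[2] = FeatureMap(np.zeros((3, 2, 2)), 16)
        with pytest.raises(ShapeError, match="P4"):
            fuse_pyramid(levels, np.zeros((1, 4, 1, 1)))

    def test_toy_fusion_matches_hand_computed_sum(self):
        """Unit 1x1 weights + nearest upsampling: output = sum of aligned inputs."""
        p2 = np.arange(16, dtype=float).reshape(1, 4, 4)
        p3 = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        p4 = np.array([[[10.0]]])
        p5 = np.array([[[100.0]]])
        levels = [FeatureMap(p2, 4), FeatureMap(p3, 8),
                  FeatureMap(p4, 16), FeatureMap(p5, 32)]
        fused = fuse_pyramid(levels, np.ones((1, 4, 1, 1)), mode="nearest")
        expected = p2[0] + np.repeat(np.repeat(p3[0], 2, 0), 2, 1) + 10.0 + 100.0
        assert np.allclose(fused.data[0], expected)


class TestWholePhase:
    def test_saturated_gate_is_identity(self, rng):
        f = FeatureMap(rng.normal(size=(3, 5, 5)), 4)
        w_sw = np.ones((1, 3, 1, 1))
        w_gate = np.zeros((1, 1, 1, 1))
        _, f_w = whole_phase(f, w_sw, w_gate, b_gate=np.array([60.0]))
        assert np.allclose(f_w.data, f.data, atol=1e-9)

    def test_null_gate_zeroes_features(self, rng):
        f = FeatureMap(rng.normal(size=(3, 5, 5)), 4)
        _, f_w = whole_phase(f, np.ones((1, 3, 1, 1)), np.zeros((1, 1, 1, 1)),
                             b_gate=np.array([-60.0]))
        assert np.allclose(f_w.data, 0.0, atol=1e-9)

    def test_gate_bound_holds_for_random_weights(self, rng):
        """|f_w| <= |f| elementwise because the gate is a sigmoid in (0,1)."""
        for _ in range(5):
            f = FeatureMap(rng.normal(size=(3, 5, 5)), 4)
            w_sw = rng.normal(size=(1, 3, 1, 1))
            w_gate = rng.normal(size=(1, 1, 1, 1))
            _, f_w = whole_phase(f, w_sw, w_gate, b_sw=rng.normal(size=1),
                                 b_gate=rng.normal(size=1))
            assert np.all(np.abs(f_w.data) <= np.abs(f.data) + 1e-12)


class TestPartPhase:
    def test_zero_input_zero_bias_gives_zero_logits(self):
        f_w = FeatureMap(np.zeros((2, 6, 6)), 4)
        _, s_p = part_phase(f_w, np.ones((2, 2, 3, 3)), np.ones((2, 2, 3, 3)),
                            np.ones((4, 2, 1, 1)))
        assert s_p.shape == (4, 6, 6)
        assert np.allclose(s_p, 0.0)

    def test_dilated_conv_receptive_field_spans_five_pixels(self):
        impulse = ag.Tensor(np.zeros((1, 11, 11)))
        impulse.data[0, 5, 5] = 1.0
        w = ag.Tensor(np.ones((1, 1, 3, 3)))
        out = ag.conv2d(impulse, w, dilation=2).data[0]
        rows = np.nonzero(out.sum(axis=1))[0]
        assert rows.min() == 3 and rows.max() == 7  # span of 5 pixels

    def test_default_rates_must_be_one_two(self):
        f_w = FeatureMap(np.zeros((2, 6, 6)), 4)
        with pytest.raises(ValueError):
            part_phase(f_w, np.ones((2, 2, 3, 3)), np.ones((2, 2, 3, 3)),
                       np.ones((4, 2, 1, 1)), rates=(2, 4))


class TestLosses:
    def test_constant_half_prediction_gives_ln2(self):
        probs = np.full((4, 3, 3), 0.5)
        gt = np.random.default_rng(0).integers(0, 4, size=(3, 3))
        assert nn.part_loss(probs, gt) == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_near_zero(self):
        gt = np.array([[0, 1], [2, 3]])
        probs = nn.one_hot_parts(gt)
        assert nn.part_loss(probs, gt) <= 1e-6

    def test_hand_computed_two_pixel_case(self):
        # S = (0.9, 0.2) against S~ = (1, 0): -(ln 0.9 + ln 0.8)/2 = 0.1643
        probs = np.array([0.9, 0.2]).reshape(1, 1, 2)
        targets = np.array([1.0, 0.0]).reshape(1, 1, 2)
        loss = -np.mean(targets * np.log(np.clip(probs, 1e-7, 1 - 1e-7))
                        + (1 - targets) * np.log(1 - np.clip(probs, 1e-7, 1 - 1e-7)))
        assert loss == pytest.approx(0.16425, abs=1e-4)
        t = ag.bce_with_probs(ag.Tensor(probs), targets)
        assert float(t.data) == pytest.approx(0.16425, abs=1e-4)

    def test_total_loss_combinations(self):
        assert nn.total_loss(0.5, 0.25, nn.LossConfig(1.0, 1.0)) == pytest.approx(0.75)
        assert nn.total_loss(0.5, 0.25, nn.LossConfig(1.0, 0.0)) == pytest.approx(0.5)
        assert nn.instance_loss(0.1, 0.2, 0.3) == pytest.approx(0.6)

    def test_invalid_loss_weights(self):
        with pytest.raises(ValueError):
            nn.total_loss(1.0, 1.0, nn.LossConfig(-1.0, 1.0))
        with pytest.raises(ValueError):
            nn.total_loss(1.0, 1.0, nn.LossConfig(0.0, 0.0))


class TestAlignAndFuse:
    def test_full_mask_gives_global_argmax(self, rng):
        logits = rng.normal(size=(4, 3, 3))
        inst = nn.InstancePrediction((0, 0, 3, 3), 1.0, np.ones((3, 3), bool))
        [res] = nn.align_and_fuse([inst], logits)
        assert np.array_equal(res.labels, np.argmax(logits, axis=0))

    def test_empty_mask_gives_empty_parsing(self, rng):
        logits = rng.normal(size=(4, 3, 3))
        inst = nn.InstancePrediction((0, 0, 1, 1), 1.0, np.zeros((3, 3), bool))
        [res] = nn.align_and_fuse([inst], logits)
        assert res.labels.max() == 0

    def test_hand_set_three_by_three(self):
        logits = np.zeros((4, 3, 3))
        logits[1, 0, :] = 5.0  # head wins row 0
        logits[3, 2, :] = 5.0  # tail wins row 2
        mask = np.zeros((3, 3), bool)
        mask[:, :2] = True
        inst = nn.InstancePrediction((0, 0, 3, 2), 1.0, mask)
        [res] = nn.align_and_fuse([inst], logits)
        expected = np.array([[1, 1, 0], [0, 0, 0], [3, 3, 0]])
        assert np.array_equal(res.labels, expected)

    def test_support_containment(self, rng, tiny_scenes):
        logits = rng.normal(size=(4, *tiny_scenes[0].part_map.shape))
        insts = [nn.InstancePrediction((0, 0, 5, 5), 0.9,
                                       tiny_scenes[0].instance_map == 1)]
        [res] = nn.align_and_fuse(insts, logits)
        assert np.all((res.labels > 0) <= insts[0].mask)

    def test_resolution_mismatch_raises(self, rng):
        inst = nn.InstancePrediction((0, 0, 2, 2), 1.0, np.ones((4, 4), bool))
        with pytest.raises(ShapeError):
            nn.align_and_fuse([inst], rng.normal(size=(4, 3, 3)))


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_scenes):
        net = nn.PartParsingNet(nn.NetConfig(seed=0))
        before = {k: v.copy() for k, v in net.state_dict().items()}
        nn.train_tiny(tiny_scenes[:1], nn.TrainConfig(epochs=2, lr=0.0,
                                                      weight_decay=0.0, seed=0), net=net)
        for k, v in net.state_dict().items():
            assert np.allclose(v, before[k])

    def test_loss_decreases_on_small_overfit(self, tiny_scenes):
        _, log = nn.train_tiny(tiny_scenes[:2],
                               nn.TrainConfig(epochs=12, lr=5e-3, seed=0))
        assert log[-1] < log[0]

    def test_checkpoint_roundtrip(self, tiny_scenes, tmp_path):
        net, _ = nn.train_tiny(tiny_scenes[:1],
                               nn.TrainConfig(epochs=2, lr=1e-3, seed=1),
                               checkpoint_path=tmp_path / "m.npz")
        loaded = nn.load_checkpoint(tmp_path / "m.npz")
        img = tiny_scenes[0].image
        assert np.allclose(loaded.predict_foreground_prob(img),
                           net.predict_foreground_prob(img))

    def test_instance_branch_on_disjoint_scene(self, tiny_scenes):
        prob = np.zeros((40, 40))
        prob[5:15, 5:15] = 0.9
        prob[25:35, 25:35] = 0.8
        dets = nn.extract_instances(prob)
        assert len(dets) == 2
        assert dets[0].score >= dets[1].score
        assert all(d.label == "sperm" for d in dets)

    def test_empty_image_no_detections(self):
        dets = nn.extract_instances(np.zeros((30, 30)))
        assert dets == []
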
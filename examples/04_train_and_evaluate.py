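"""Train the tiny part-parsing network on synthetic scenes and evaluate it.

Overfits a small pyramid-fusion network on two desk-scale scenes, then
reports the parsing metrics (mIoU, AP^p_50, AP^p_vol, PCP50) of its
predictions against the rendered ground truth.  Runs in under a minute on
one CPU core.
"""

from spermorph import GeometryRanges, GroundTruthParsing, SceneSpec, evaluate, make_scene, nn

ranges = GeometryRanges(tail_width_um=(0.9, 1.1), mid_width_um=(0.7, 0.9),
                        tail_length_um=(12.0, 16.0))
scenes = [make_scene(SceneSpec(width=144, height=112, count_range=(2, 2),
                               pixel_size_um=0.2, blur_sigma_px=0.8,
                               noise_sd=0.01, seed=s, ranges=ranges))
          for s in (0, 1)]

net, log = nn.train_tiny(scenes, nn.TrainConfig(epochs=150, lr=5e-3, seed=0))
print(f"training loss: {log[0]:.3f} -> {log[-1]:.4f} over {len(log)} epochs")

for i, scene in enumerate(scenes):
    results, part_map = nn.parse_image(net, scene.image)
    gt = GroundTruthParsing(scene.instance_map, scene.part_map)
    rep = evaluate(results, gt, pred_part_map=part_map)
    print(f"scene {i}: {len(results)} detections / {len(gt.instance_ids)} GT | "
          f"mIoU {rep.miou:.1f}%  AP50 {rep.ap_50:.1f}%  "
          f"APvol {rep.ap_vol:.1f}%  PCP50 {rep.pcp_50:.1f}%")
print("\nSemantic parsing (mIoU) is near-perfect after overfitting; the "
      "instance metrics drop when two touching sperm merge into one "
      "connected component, which is exactly what they are meant to expose.")
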
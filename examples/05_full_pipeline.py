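"""End-to-end run: synthesize, parse, measure, and enhance over 120 frames.

Renders one scene, measures every instance, then simulates the 2-second /
60 fps acquisition of the same sperm rotating at 3.7 Hz: each frame is
rendered and measured, instances are tracked by nearest centroid, and each
parameter's per-frame series goes through the accuracy-enhancement
pipeline.  The printed table compares the naive per-series maximum against
the enhanced estimate for every head parameter.
"""

from spermorph import ProjectConfig, run_pipeline
from spermorph.config import SequenceSection, SynthSection

cfg = ProjectConfig(
    seed=3,
    synth=SynthSection(width=260, height=220, count_min=2, count_max=2,
                       pixel_size_um=0.25, n_scenes=1),
    sequence=SequenceSection(n_frames=120),
)
result = run_pipeline(cfg, write_artifacts=False)

print(f"scenes: {len(result.scenes)}, measured instances: "
      f"{sum(len(m) for m in result.measurements)}")
print(f"\n{'instance/parameter':28s} {'truth':>7s} {'naive':>7s} "
      f"{'enhanced':>8s} {'err naive':>9s} {'err enh':>8s}")
for r in result.sequence_results:
    if not r.parameter.startswith("head"):
        continue
    print(f"{r.instance_id}/{r.parameter:26s} {r.true_value:7.2f} "
          f"{r.naive_max:7.2f} {r.enhanced:8.2f} "
          f"{r.naive_error_pct:8.1f}% {r.enhanced_error_pct:7.1f}%")
print("\nEnhancement helps most where per-frame measurement fluctuates "
      "(rotation, jitter, blur); residual error reflects rasterization "
      "bias that no temporal filter can remove.")
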
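"""Robust peak extraction from a noisy periodic parameter series.

A rotating sperm's apparent head width oscillates at ~3.7 Hz; its true width
is the per-cycle peak.  This script generates a contaminated 120-frame
series (60 fps, 2 s), runs the enhancement pipeline (per-cycle peak regions
-> IQR outlier fence -> Gaussian smoothing -> maximum) and compares the
result against the naive maximum of the raw series.
"""

from spermorph import (
    MotionSignalSpec,
    ParameterSeries,
    enhance,
    generate_motion_signal,
    relative_error,
)

spec = MotionSignalSpec(seed=4)  # 3.7 Hz, 120 frames, 5% noise, 5% outliers at 3x
signal = generate_motion_signal(spec)
series = ParameterSeries("head_width_px", signal.values)
est = enhance(series)

naive = signal.values.max()
print(f"true peak value      : {signal.true_max:.3f}")
print(f"naive max of series  : {naive:.3f}  "
      f"(error {relative_error(naive, signal.true_max):.2f}%)")
print(f"enhanced estimate Y  : {est.y:.3f}  "
      f"(error {relative_error(est.y, signal.true_max):.2f}%)")
print(f"cycles found         : {est.regions.n_cycles} "
      f"(peak frames {list(est.regions.peak_indices)})")
print("stages               :", " -> ".join(est.stage_order))
print("\nThe naive maximum chases outlier spikes; the enhanced estimate "
      "tracks the true per-cycle peak.")
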
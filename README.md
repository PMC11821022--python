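# spermorph

Stain-free sperm morphology measurement: instance-level part parsing,
per-part morphometry, and measurement-accuracy enhancement for label-free
microscopy of motile sperm.

## What it does

Selecting sperm for ICSI/IVF requires quantitative morphology — head
length/width/ellipticity, midpiece length/width/angle, tail
length/width/angle — without staining, which damages the cell. Label-free
imaging at selection magnification is low-contrast and blurry, so
`spermorph` combines three pieces:

1. **A dual-branch part-parsing network** (`spermorph.nn`): a feature
   pyramid fused to one map `f`; a *whole phase* that derives a coarse
   cell logit `S_w` and gates the features, `f_w = σ(conv(S_w)) ⊙ f`; a
   *part phase* of dilated 3×3 convolutions (rates 1, 2) producing
   4-class part logits `S_p`; and instance fusion
   `S_final = S_inst ⊙ S_p` that restricts part labels to each detected
   instance. Trained with `L_total = λ_inst L_inst + λ_part L_part`, the
   part term a one-vs-rest binary cross-entropy. Implemented in pure
   numpy with a small autodiff engine — small enough to train on a
   laptop CPU.
2. **Morphometry** (`spermorph.morphometry`): moments-ellipse +
   minimum-area-rectangle fitting for head and midpiece, and a Steger
   sub-pixel centerline tracer (Hessian ridge detection, orientation-
   consistent linking, normal-direction width) for the tail.
3. **Accuracy enhancement** (`spermorph.enhancement`): a rotating sperm's
   apparent dimensions oscillate at ~3.7 Hz, one local maximum per
   rotation. From a 120-frame series X (2 s at 60 fps) the pipeline
   extracts per-cycle peak regions X′, removes outliers with the 1.5·IQR
   fence (X″), Gaussian-smooths within regions (X‴), and reports the
   robust maximum Y = max X‴ — instead of the outlier-chasing naive
   max X. Relative error `|V_M − V_GT|/V_GT × 100` and its reduction
   `(before − after)/before × 100` quantify the gain.

A seeded synthetic generator (`spermorph.synth`) renders scenes with
pixel-exact ground truth and periodic parameter series with known peaks,
so the whole chain is testable end to end; `spermorph.evaluation`
implements the parsing metrics (mIoU, AP^p_50, AP^p_vol, PCP50).

## Worked example

Robust peak extraction from a contaminated series
(`examples/02_enhance_series.py`):

```text
true peak value      : 12.000
naive max of series  : 17.356  (error 44.64%)
enhanced estimate Y  : 12.005  (error 0.04%)
cycles found         : 6 (peak frames [7, 24, 41, 57, 76, 102])
stages               : local_maximum_extraction -> outlier_removal -> gaussian_filtering -> maximum_extraction
```

The naive maximum lands on a +3-amplitude outlier frame (44.6% error);
the enhanced estimate recovers the true per-cycle peak to 0.04%.

Training and evaluating the tiny parser
(`examples/04_train_and_evaluate.py`):

```text
training loss: 1.790 -> 0.0426 over 150 epochs
scene 0: 1 detections / 2 GT | mIoU 92.6%  AP50 0.0%  APvol 22.2%  PCP50 33.3%
scene 1: 2 detections / 2 GT | mIoU 92.1%  AP50 100.0%  APvol 91.7%  PCP50 100.0%
```

Semantic parsing (mIoU) is near-perfect after overfitting; on scene 0 two
touching sperm merge into one detection and the instance-level metrics
expose it.

The other examples cover scene synthesis (`01`), morphometry against
analytic ground truth (`03`), and the full 120-frame pipeline (`05`). A
thin CLI wraps the same calls: `spermorph synth|train-tiny|infer|measure|
enhance|report-errors|evaluate|run`.

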
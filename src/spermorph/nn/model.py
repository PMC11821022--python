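"""The dual-branch part-parsing model.

The architecture follows a coarse-to-fine scheme on top of a feature
pyramid:

* **pyramid fusion** — levels P3..P5 are upsampled to P2's resolution,
  concatenated with P2 and reduced by a learned 1x1 convolution into one
  fused feature map ``f``;
* **whole phase** — a 1x1 convolution of ``f`` gives a coarse whole-cell
  mask logit ``S_w``; a sigmoid gate derived from ``S_w`` modulates ``f``
  elementwise into ``f_w``, focusing the features on cell regions;
* **part phase** — a cascade of two 3x3 dilated convolutions (rates 1, 2)
  expands the receptive field into ``f_p``, and a 1x1 convolution produces
  the 4-channel part logits ``S_p`` (background, head, midpiece, tail);
* **alignment fusion** — per detected instance, the part labels are the
  channel argmax of ``S_p`` restricted to the instance mask support
  (``S_final = S_inst * S_p``).

Each stage exists both as a pure function on arrays (the algebraic
contract) and inside :class:`PartParsingNet`, whose parameters are trained
with the autograd engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor

N_PART_CLASSES = 4  # background, head, midpiece, tail


class ShapeError(ValueError):
    pass


@dataclass
class FeatureMap:
    """A (channels, height, width) feature grid with its image stride."""

    data: np.ndarray
    stride: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] <= 0:
            raise ShapeError("feature map must be (channels, H, W)")
        s = self.stride
        if s <= 0 or (s & (s - 1)) != 0:
            raise ShapeError("stride must be a positive power of two")


# ---------------------------------------------------------------------------
# Functional stage contracts (shared by the trained network)
# ---------------------------------------------------------------------------

def _fuse(tensors: list[Tensor], strides: list[int], weight: Tensor,
          bias: Optional[Tensor], mode: str) -> Tensor:
    target = tensors[0].data.shape[1:]
    ups = [tensors[0]] + [ag.resize(t, target, mode) for t in tensors[1:]]
    return ag.conv2d(ag.concat_channels(ups), weight, bias)


def fuse_pyramid(pyramid: list[FeatureMap], weight: np.ndarray,
                 bias: Optional[np.ndarray] = None,
                 mode: str = "bilinear") -> FeatureMap:
    """Upsample P3..P5 to P2 resolution, concatenate, reduce by 1x1 conv.

    ``weight`` has shape (out_channels, sum of level channels, 1, 1).
    Raises a :class:`ShapeError` naming the offending level on channel
    mismatch.
    """
    if len(pyramid) < 2:
        raise ShapeError("pyramid fusion needs at least two levels")
    c0 = pyramid[0].data.shape[0]
    for i, level in enumerate(pyramid[1:], start=3):
        if level.data.shape[0] != c0:
            raise ShapeError(
                f"P{i} has {level.data.shape[0]} channels, expected {c0} (as P2)")
    weight = np.asarray(weight, dtype=float)
    if weight.shape[1] != c0 * len(pyramid):
        raise ShapeError(
            f"1x1 weight expects {weight.shape[1]} input channels, "
            f"pyramid concatenation has {c0 * len(pyramid)}")
    out = _fuse([Tensor(l.data) for l in pyramid], [l.stride for l in pyramid],
                Tensor(weight), None if bias is None else Tensor(bias), mode)
    return FeatureMap(out.data, pyramid[0].stride)


def _whole(f: Tensor, w_sw: Tensor, b_sw: Optional[Tensor],
           w_gate: Tensor, b_gate: Optional[Tensor]) -> tuple[Tensor, Tensor]:
    s_w = ag.conv2d(f, w_sw, b_sw)
    gate = ag.sigmoid(ag.conv2d(s_w, w_gate, b_gate))
    return s_w, ag.mul(gate, f)


def whole_phase(f: FeatureMap, w_sw: np.ndarray, w_gate: np.ndarray,
                b_sw: Optional[np.ndarray] = None,
                b_gate: Optional[np.ndarray] = None) -> tuple[np.ndarray, FeatureMap]:
    """Coarse whole-cell logit S_w and the sigmoid-gated feature f_w.

    The 1-channel gate broadcasts across f's channels; because the gate is
    a sigmoid in (0, 1), |f_w| <= |f| holds elementwise.
    """
    s_w, f_w = _whole(Tensor(f.data), Tensor(w_sw),
                      None if b_sw is None else Tensor(b_sw),
                      Tensor(w_gate), None if b_gate is None else Tensor(b_gate))
    return s_w.data, FeatureMap(f_w.data, f.stride)


def _part(f_w: Tensor, w_d1, b_d1, w_d2, b_d2, w_sp, b_sp,
          rates: tuple[int, int]) -> tuple[Tensor, Tensor]:
    h = ag.relu(ag.conv2d(f_w, w_d1, b_d1, dilation=rates[0]))
    f_p = ag.relu(ag.conv2d(h, w_d2, b_d2, dilation=rates[1]))
    return f_p, ag.conv2d(f_p, w_sp, b_sp)


def part_phase(f_w: FeatureMap, w_d1: np.ndarray, w_d2: np.ndarray,
               w_sp: np.ndarray, rates: tuple[int, int] = (1, 2),
               b_d1=None, b_d2=None, b_sp=None) -> tuple[FeatureMap, np.ndarray]:
    """Dilated-convolution cascade f_p and the 4-channel part logits S_p."""
    if tuple(rates) != (1, 2):
        raise ValueError("the dilated cascade uses rates (1, 2)")
    if w_sp.shape[0] != N_PART_CLASSES:
        raise ShapeError(f"part logits need {N_PART_CLASSES} channels")
    conv = lambda a: None if a is None else Tensor(np.asarray(a, dtype=float))
    f_p, s_p = _part(Tensor(f_w.data), Tensor(w_d1), conv(b_d1), Tensor(w_d2),
                     conv(b_d2), Tensor(w_sp), conv(b_sp), tuple(rates))
    return FeatureMap(f_p.data, f_w.stride), s_p.data


# ---------------------------------------------------------------------------
# The trainable network
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Architecture hyperparameters.

    The default is a deliberately small configuration for desk-scale
    training on synthetic scenes: an 8-channel 4-stage backbone whose first
    pyramid level has stride ``base_stride`` (1 keeps full resolution, 4
    mimics a conventional P2).  ``normalize_mean``/``std`` default to the
    ImageNet statistics for 3-channel input; single-channel images use
    their channel means.
    """

    in_channels: int = 1
    base_channels: int = 8
    pyramid_channels: int = 8
    base_stride: int = 1
    upsample: str = "bilinear"
    dilation_rates: tuple[int, int] = (1, 2)
    seed: int = 0
    mask_threshold: float = 0.5
    score_threshold: float = 0.5
    min_instance_px: int = 10
    normalize_mean: tuple[float, ...] = (0.485, 0.456, 0.406)
    normalize_std: tuple[float, ...] = (0.229, 0.224, 0.225)
    normalize: bool = False


class PartParsingNet:
    """Tiny pyramid-fusion part-parsing network with explicit parameters."""

    VERSION = "spermorph-net-1"

    def __init__(self, cfg: NetConfig | None = None):
        self.cfg = cfg or NetConfig()
        rng = np.random.default_rng(self.cfg.seed)
        c = self.cfg.base_channels
        pc = self.cfg.pyramid_channels
        self.params: dict[str, Tensor] = {}

        def P(name, shape, scale):
            self.params[name] = ag.parameter(shape, rng, scale)
            return self.params[name]

        def zeros(name, n):
            self.params[name] = ag.parameter(np.zeros(n))
            return self.params[name]

        fan = 3 * 3 * self.cfg.in_channels
        P("stem.w", (c, self.cfg.in_channels, 3, 3), np.sqrt(2.0 / fan))
        zeros("stem.b", c)
        for i in (3, 4, 5):
            P(f"stage{i}.w", (c, c, 3, 3), np.sqrt(2.0 / (9 * c)))
            zeros(f"stage{i}.b", c)
        for i in (2, 3, 4, 5):
            P(f"lat{i}.w", (pc, c, 1, 1), np.sqrt(2.0 / c))
            zeros(f"lat{i}.b", pc)
        P("fuse.w", (pc, 4 * pc, 1, 1), np.sqrt(2.0 / (4 * pc)))
        zeros("fuse.b", pc)
        P("sw.w", (1, pc, 1, 1), np.sqrt(2.0 / pc))
        zeros("sw.b", 1)
        P("gate.w", (1, 1, 1, 1), 1.0)
        zeros("gate.b", 1)
        P("d1.w", (pc, pc, 3, 3), np.sqrt(2.0 / (9 * pc)))
        zeros("d1.b", pc)
        P("d2.w", (pc, pc, 3, 3), np.sqrt(2.0 / (9 * pc)))
        zeros("d2.b", pc)
        P("sp.w", (N_PART_CLASSES, pc, 1, 1), np.sqrt(2.0 / pc))
        zeros("sp.b", N_PART_CLASSES)

    # -- plumbing ----------------------------------------------------------
    def _prepare(self, image: np.ndarray) -> Tensor:
        image = np.asarray(image, dtype=float)
        if image.ndim == 2:
            image = image[None]
        if image.shape[0] != self.cfg.in_channels:
            raise ShapeError(
                f"expected {self.cfg.in_channels}-channel input, got {image.shape[0]}")
        if self.cfg.normalize:
            mean = np.array(self.cfg.normalize_mean)
            std = np.array(self.cfg.normalize_std)
            if image.shape[0] == 1:
                mean, std = np.array([mean.mean()]), np.array([std.mean()])
            image = (image - mean[:, None, None]) / std[:, None, None]
        return Tensor(image)

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r} in checkpoint")
            self.params[k].data = np.asarray(v, dtype=float)

    # -- forward -----------------------------------------------------------
    def forward(self, image: np.ndarray) -> dict[str, Tensor]:
        """Run the full model; returns all intermediate tensors by name."""
        p = self.params
        x = self._prepare(image)
        for _ in range(int(np.log2(self.cfg.base_stride))):
            x = ag.avg_pool2(x)
        c2 = ag.relu(ag.conv2d(x, p["stem.w"], p["stem.b"]))
        c3 = ag.relu(ag.conv2d(ag.avg_pool2(c2), p["stage3.w"], p["stage3.b"]))
        c4 = ag.relu(ag.conv2d(ag.avg_pool2(c3), p["stage4.w"], p["stage4.b"]))
        c5 = ag.relu(ag.conv2d(ag.avg_pool2(c4), p["stage5.w"], p["stage5.b"]))
        pyr = [ag.conv2d(t, p[f"lat{i}.w"], p[f"lat{i}.b"])
               for i, t in zip((2, 3, 4, 5), (c2, c3, c4, c5))]
        f = _fuse(pyr, [], p["fuse.w"], p["fuse.b"], self.cfg.upsample)
        s_w, f_w = _whole(f, p["sw.w"], p["sw.b"], p["gate.w"], p["gate.b"])
        f_p, s_p = _part(f_w, p["d1.w"], p["d1.b"], p["d2.w"], p["d2.b"],
                         p["sp.w"], p["sp.b"], self.cfg.dilation_rates)
        full = image.shape[-2:]
        return {
            "f": f, "s_w": s_w, "f_w": f_w, "f_p": f_p, "s_p": s_p,
            "s_w_up": ag.resize(s_w, full, self.cfg.upsample),
            "s_p_up": ag.resize(s_p, full, self.cfg.upsample),
        }

    def predict_part_map(self, image: np.ndarray) -> np.ndarray:
        """Semantic part labels at image resolution (channel argmax of S_p)."""
        out = self.forward(image)
        return np.argmax(out["s_p_up"].data, axis=0)

    def predict_foreground_prob(self, image: np.ndarray) -> np.ndarray:
        out = self.forward(image)
        return 1.0 / (1.0 + np.exp(-out["s_w_up"].data[0]))
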
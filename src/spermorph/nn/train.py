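"""Desk-scale training of the part-parsing network on synthetic scenes.

The optimizer is AdamW (decoupled weight decay) with the step-decay
schedule: the learning rate drops by 10x at 60% and 80% of the epoch
budget.  The only default augmentation is a random horizontal flip.
Training aborts with a diagnostic if the loss turns non-finite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .losses import LossConfig, one_hot_parts
from .model import NetConfig, PartParsingNet

CHECKPOINT_VERSION = "spermorph-ckpt-1"


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-4
    weight_decay: float = 1e-4
    lr_decay: float = 0.1
    lr_milestones: tuple[float, float] = (0.6, 0.8)  # fractions of the epoch budget
    flip_augment: bool = True
    #: rebalance the part BCE by upweighting each class's positive pixels to
    #: its negatives (capped); thin parts are <2% of pixels otherwise
    balance_classes: bool = True
    pos_weight_cap: float = 50.0
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


class AdamW:
    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def _scene_loss(net: PartParsingNet, image: np.ndarray, part_map: np.ndarray,
                loss_cfg: LossConfig, pos_weight=None):
    """Differentiable total loss for one scene.

    The part loss is the one-vs-rest BCE of sigmoid(S_p), optionally with
    per-channel positive weighting; the instance loss here reduces to its
    mask term — the BCE of the whole-cell logit S_w against the foreground
    map (the proposal-free instance head has no box or class parameters to
    regress).
    """
    out = net.forward(image)
    targets = one_hot_parts(part_map)
    l_part = ag.bce_with_probs(ag.sigmoid(out["s_p_up"]), targets,
                               pos_weight=pos_weight)
    fg = (np.asarray(part_map) > 0).astype(float)[None]
    l_mask = ag.bce_with_probs(ag.sigmoid(out["s_w_up"]), fg)
    loss_cfg.validate()
    return ag.scalar_sum([l_mask, l_part],
                         [loss_cfg.lambda_inst, loss_cfg.lambda_part])


def train_tiny(scenes: Sequence, cfg: TrainConfig | None = None,
               net: PartParsingNet | None = None,
               checkpoint_path: Optional[str | Path] = None,
               ) -> tuple[PartParsingNet, list[float]]:
    """Overfit a small network on a handful of synthetic scenes.

    ``scenes`` is a sequence of objects with ``image`` and ``part_map``
    attributes (e.g. :class:`~spermorph.synth.RenderedScene`).  Returns the
    trained network and the per-epoch mean loss log; optionally writes a
    versioned ``.npz`` checkpoint.
    """
    cfg = cfg or TrainConfig()
    net = net or PartParsingNet(NetConfig(seed=cfg.seed))
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(net.parameters(), cfg.lr, cfg.weight_decay)
    pos_weight = None
    if cfg.balance_classes:
        counts = np.zeros(4)
        total = 0
        for scene in scenes:
            counts += np.bincount(np.asarray(scene.part_map).ravel(), minlength=4)[:4]
            total += np.asarray(scene.part_map).size
        with np.errstate(divide="ignore"):
            w = np.where(counts > 0, (total - counts) / np.maximum(counts, 1), 1.0)
        pos_weight = np.clip(w, 1.0, cfg.pos_weight_cap)[:, None, None]
    milestones = {int(cfg.epochs * m) for m in cfg.lr_milestones}
    log: list[float] = []
    for epoch in range(cfg.epochs):
        if epoch in milestones:
            opt.lr *= cfg.lr_decay
        losses = []
        for idx in rng.permutation(len(scenes)):
            scene = scenes[idx]
            image, part_map = scene.image, scene.part_map
            if cfg.flip_augment and rng.random() < 0.5:
                image, part_map = image[:, ::-1], part_map[:, ::-1]
            loss = _scene_loss(net, image, part_map, cfg.loss, pos_weight)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}")
            for p in net.parameters().values():
                p.grad = np.zeros_like(p.data)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path, train_config=cfg, loss_log=log)
    return net, log


def save_checkpoint(net: PartParsingNet, path: str | Path,
                    train_config: TrainConfig | None = None,
                    loss_log: Optional[list[float]] = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "net_config": asdict(net.cfg),
        "train_config": asdict(train_config) if train_config else None,
        "loss_log": loss_log,
    }
    np.savez(path, __meta__=json.dumps(meta), **net.state_dict())


def load_checkpoint(path: str | Path) -> PartParsingNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}")
        nc = meta["net_config"]
        for key in ("dilation_rates", "normalize_mean", "normalize_std"):
            nc[key] = tuple(nc[key])
        net = PartParsingNet(NetConfig(**nc))
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net
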
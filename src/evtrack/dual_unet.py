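"""Dual-branch U-Net training: losses, aggregation, augmentation, loop.

One network is trained on a single *aggregated* channel — the per-pixel
maximum of the min-max-normalized nuclei, EV and merge planes — whose targets
merge all entity instances (cells, nuclei, EVs, with smaller entities taking
priority where they overlap larger ones).  At inference the same network is
applied to each channel separately (see :mod:`evtrack.fusion`).

The regressive branch is trained with a smooth L1 loss against the
per-instance normalized distance map; the categorical branch with a Dice loss
against the background/interior/border map (optionally combined with
cross-entropy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import DualUNet, Adam, sigmoid, softmax_channels
from .synthetic import MultiChannelFrame, SceneTruth
from .targets import distance_target, border_target

DEFAULT_BORDER_WIDTHS = {"cells": 2, "nuclei": 2, "evs": 1}


@dataclass
class ModelConfig:
    depth: int = 2
    base_features: int = 16
    in_channels: int = 1
    n_classes: int = 3
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (w_reg, w_cls)
    lr: float = 1e-3
    batch_size: int = 2
    smooth_l1_beta: float = 1.0
    reg_fg_weight: float = 15.0   # target-proportional pixel weight in training
    dice_eps: float = 1e-6
    cls_loss: str = "dice"                            # "dice" or "dice+ce"

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_features < 8:
            raise ValueError("base_features must be >= 8")
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss_weights must be > 0")
        if self.cls_loss not in ("dice", "dice+ce"):
            raise ValueError(f"unknown cls_loss: {self.cls_loss!r}")


@dataclass
class AugmentConfig:
    """Per-transform application probabilities (defaults lie in [0.25, 0.3])."""

    p_flip: float = 0.3
    p_contrast: float = 0.25
    p_scale: float = 0.25
    p_blur: float = 0.28
    p_noise: float = 0.28

    def validate(self) -> None:
        for name in ("p_flip", "p_contrast", "p_scale", "p_blur", "p_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TrainingRun:
    model: DualUNet
    history: list[dict[str, float]]
    seed: int
    config: ModelConfig


# ------------------------------------------------------------------- losses


def _onehot(target: np.ndarray, n_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(n_classes, dtype=np.float64)[target], -1, 0)


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss: 1 - mean over classes of (2*sum(p*t)+eps)/(sum p + sum t + eps).

    ``pred`` is a (C, H, W) per-pixel probability simplex; ``target`` an
    (H, W) integer class map.  Lies in [0, 1]; 0 for a one-hot prediction of
    the target, 1 for a prediction disjoint from it on every class present.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.ndim != 3 or pred.shape[1:] != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    t = _onehot(target, pred.shape[0])
    inter = (pred * t).sum(axis=(1, 2))
    denom = pred.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
    return float(1.0 - np.mean((2.0 * inter + eps) / (denom + eps)))


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0) -> float:
    """Huber-style smooth L1: mean of 0.5*d^2/beta for |d| < beta, else |d| - 0.5*beta."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    d = pred - target
    ad = np.abs(d)
    return float(np.mean(np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)))


def _dice_loss_batched(p: np.ndarray, t: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Batched loss and gradient wrt probabilities.  p, t: (N, C, H, W)."""
    inter = (p * t).sum(axis=(2, 3))                       # (N, C)
    denom = p.sum(axis=(2, 3)) + t.sum(axis=(2, 3))        # (N, C)
    num = 2.0 * inter + eps
    den = denom + eps
    n, c = inter.shape
    loss = float(np.mean(1.0 - (num / den).mean(axis=1)))
    g = -(2.0 * t * den[:, :, None, None] - num[:, :, None, None]) / (den ** 2)[:, :, None, None]
    return loss, g / (n * c)


def _smooth_l1_batched(pred: np.ndarray, target: np.ndarray, beta: float,
                       fg_weight: float = 0.0) -> tuple[float, np.ndarray]:
    """Smooth L1 with optional target-proportional pixel weights.

    With ``fg_weight`` > 0 a pixel of target value t carries weight
    1 + fg_weight * t (mean-normalized).  Instance distance peaks occupy a
    tiny fraction of a microscopy frame; without the reweighting the
    regression branch is dominated by background and systematically
    undershoots the peaks the seed thresholds rely on.
    """
    d = pred - target
    ad = np.abs(d)
    per_px = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    g = np.where(ad < beta, d / beta, np.sign(d))
    if fg_weight > 0:
        w = 1.0 + fg_weight * target
        w = w / w.mean()
        per_px = per_px * w
        g = g * w
    return float(np.mean(per_px)), g / d.size


def _ce_batched(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy and gradient wrt probabilities (chained through softmax
    later via the generic simplex rule)."""
    eps = 1e-12
    n_pix = p.shape[0] * p.shape[2] * p.shape[3]
    loss = float(-(t * np.log(p + eps)).sum() / n_pix)
    g = -(t / (p + eps)) / n_pix
    return loss, g


# -------------------------------------------------------------- aggregation


def _minmax(plane: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if hi <= lo:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def aggregate_channel(frame: MultiChannelFrame) -> np.ndarray:
    """Per-pixel maximum of the three min-max-normalized planes, in [0, 1].

    A constant plane normalizes to zero and therefore contributes nothing.
    """
    return np.maximum(np.maximum(_minmax(frame.nuclei_plane), _minmax(frame.ev_plane)),
                      _minmax(frame.merge_plane))


def training_targets(truth: SceneTruth,
                     border_widths: dict[str, int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated-channel targets merging all entity instances.

    Per-entity distance and border maps are built with entity-specific border
    widths, then overlaid small-over-large (cells, then nuclei, then EVs), so
    EV puncta keep their own distance peaks and border rings even inside a
    cell body.
    """
    bw = dict(DEFAULT_BORDER_WIDTHS)
    if border_widths:
        bw.update(border_widths)
    dmap = distance_target(truth.cells)
    cmap = border_target(truth.cells, bw["cells"])
    for labels, width in ((truth.nuclei, bw["nuclei"]), (truth.evs, bw["evs"])):
        fg = labels > 0
        if fg.any():
            dmap[fg] = distance_target(labels)[fg]
            cmap[fg] = border_target(labels, width)[fg]
    return dmap, cmap


# ------------------------------------------------------------- augmentation


def _resize_center(arr: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    """Zoom-agnostic center crop/pad back to ``shape``."""
    out = np.zeros(shape, dtype=arr.dtype)
    h, w = arr.shape
    th, tw = shape
    sy, ty = (h - th) // 2 if h > th else 0, (th - h) // 2 if th > h else 0
    sx, tx = (w - tw) // 2 if w > tw else 0, (tw - w) // 2 if tw > w else 0
    ch, cw = min(h, th), min(w, tw)
    out[ty:ty + ch, tx:tx + cw] = arr[sy:sy + ch, sx:sx + cw]
    return out


def augment(image: np.ndarray, targets: tuple[np.ndarray, np.ndarray],
            cfg: AugmentConfig, seed: int) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Stochastic augmentation of an (image, (distance map, class map)) triple.

    Geometric transforms (flip, scale) are applied identically to the image
    and both targets (nearest-neighbour for the class map); photometric
    transforms (contrast, blur, noise) touch the image only.  Each transform
    fires independently with its configured probability; all randomness comes
    from ``seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=np.float64).copy()
    dmap, cmap = targets
    dmap = np.asarray(dmap, dtype=np.float64).copy()
    cmap = np.asarray(cmap).copy()
    shape = image.shape

    if rng.uniform() < cfg.p_flip:
        axis = int(rng.integers(2))
        image, dmap, cmap = (np.flip(a, axis=axis).copy() for a in (image, dmap, cmap))
    if rng.uniform() < cfg.p_scale:
        s = float(rng.uniform(0.85, 1.15))
        image = _resize_center(ndimage.zoom(image, s, order=1), shape, 1)
        dmap = _resize_center(np.clip(ndimage.zoom(dmap, s, order=1), 0, 1), shape, 1)
        cmap = _resize_center(ndimage.zoom(cmap, s, order=0), shape, 0)
    if rng.uniform() < cfg.p_contrast:
        c = float(rng.uniform(0.7, 1.3))
        mean = image.mean()
        image = np.clip(mean + (image - mean) * c, 0.0, 1.0)
    if rng.uniform() < cfg.p_blur:
        image = ndimage.gaussian_filter(image, float(rng.uniform(0.4, 1.0)))
    if rng.uniform() < cfg.p_noise:
        image = np.clip(image + rng.normal(0.0, float(rng.uniform(0.01, 0.05)),
                                           size=image.shape), 0.0, 1.0)
    return image, (dmap, cmap)


# ----------------------------------------------------------------- training


def pad_to_multiple(arr: np.ndarray, multiple: int, mode: str = "reflect") -> tuple[np.ndarray, tuple[int, int]]:
    """Pad the trailing 2 axes up to a multiple; returns (padded, original H, W)."""
    h, w = arr.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode=mode)
    return arr, (h, w)


def _loss_and_grads(model: DualUNet, x: np.ndarray, dmap: np.ndarray,
                    cmap: np.ndarray, cfg: ModelConfig
                    ) -> tuple[float, float, float]:
    """One forward/backward pass; returns (total, dice, smooth_l1) losses.

    Gradients wrt the head logits are chained through the sigmoid (regression
    head) and the per-pixel softmax (classification head) analytically.
    """
    w_reg, w_cls = cfg.loss_weights
    reg_logit, cls_logit = model.forward(x)
    s = sigmoid(reg_logit[:, 0])
    p = softmax_channels(cls_logit.astype(np.float64))
    t = np.stack([_onehot(c, cfg.n_classes) for c in cmap])

    l_reg, g_s = _smooth_l1_batched(s, dmap, cfg.smooth_l1_beta,
                                    fg_weight=cfg.reg_fg_weight)
    l_dice, g_p = _dice_loss_batched(p, t, cfg.dice_eps)
    l_cls = l_dice
    if cfg.cls_loss == "dice+ce":
        l_ce, g_ce = _ce_batched(p, t)
        l_cls = l_dice + l_ce
        g_p = g_p + g_ce

    d_reg_logit = (w_reg * g_s * s * (1.0 - s))[:, None].astype(np.float32)
    # simplex chain rule: dL/dz_c = p_c * (g_c - sum_k g_k p_k)
    gp = w_cls * g_p
    d_cls_logit = (p * (gp - (gp * p).sum(axis=1, keepdims=True))).astype(np.float32)
    model.backward(d_reg_logit, d_cls_logit)
    return w_reg * l_reg + w_cls * l_cls, l_dice, l_reg


def train_model(dataset: list[tuple[MultiChannelFrame, SceneTruth]],
                model_cfg: ModelConfig | None = None,
                aug_cfg: AugmentConfig | None = None,
                epochs: int = 50,
                seed: int = 0,
                border_widths: dict[str, int] | None = None) -> TrainingRun:
    """Train the dual-branch network on the aggregated channel.

    Each dataset item contributes one (aggregated image, distance target,
    border-class target) triple; augmentation is re-drawn per sample per
    epoch.  The per-epoch history records the mean total, Dice and smooth-L1
    losses.  Aborts with a diagnostic if a non-finite loss appears.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    model_cfg = model_cfg or ModelConfig()
    aug_cfg = aug_cfg or AugmentConfig()
    model_cfg.validate()
    aug_cfg.validate()

    rng = np.random.default_rng(seed)
    model = DualUNet(model_cfg.depth, model_cfg.base_features,
                     model_cfg.in_channels, model_cfg.n_classes,
                     seed=int(rng.integers(2 ** 31)))
    if epochs == 0:
        return TrainingRun(model=model, history=[], seed=seed, config=model_cfg)

    mult = 2 ** (model_cfg.depth - 1)
    samples = []
    for frame, truth in dataset:
        x = aggregate_channel(frame)
        dmap, cmap = training_targets(truth, border_widths)
        samples.append((x, dmap, cmap))

    opt = Adam(model.params(), lr=model_cfg.lr)
    history: list[dict[str, float]] = []
    n = len(samples)
    bs = max(1, model_cfg.batch_size)
    for epoch in range(epochs):
        order = rng.permutation(n)
        tot = dce = sl1 = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xs, ds, cs = [], [], []
            for i in idx:
                x, d, c = samples[i]
                xa, (da, ca) = augment(x, (d, c), aug_cfg, int(rng.integers(2 ** 31)))
                xs.append(pad_to_multiple(xa, mult)[0])
                ds.append(pad_to_multiple(da, mult)[0])
                cs.append(pad_to_multiple(ca.astype(np.int64), mult, mode="constant")[0])
            xb = np.stack(xs)[:, None]
            l_tot, l_dice, l_sl1 = _loss_and_grads(model, xb, np.stack(ds),
                                                   np.stack(cs), model_cfg)
            if not np.isfinite(l_tot):
                raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
            opt.step()
            tot += l_tot
            dce += l_dice
            sl1 += l_sl1
            n_batches += 1
        history.append({"total": tot / n_batches, "dice": dce / n_batches,
                        "smooth_l1": sl1 / n_batches})
    return TrainingRun(model=model, history=history, seed=seed, config=model_cfg)


# -------------------------------------------------------------- persistence


def save_checkpoint(path: str | Path, run: TrainingRun) -> None:
    """Binary weight file plus a JSON sidecar (config, seed, history)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **run.model.state_dict())
    sidecar = {
        "config": asdict(run.config),
        "seed": run.seed,
        "history": run.history,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path) -> TrainingRun:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    cfg_d = sidecar["config"]
    cfg_d["loss_weights"] = tuple(cfg_d["loss_weights"])
    cfg = ModelConfig(**cfg_d)
    model = DualUNet(cfg.depth, cfg.base_features, cfg.in_channels, cfg.n_classes)
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return TrainingRun(model=model, history=sidecar["history"],
                       seed=sidecar["seed"], config=cfg)
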
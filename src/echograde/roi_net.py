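"""ROI-CNN: the multi-scale fully convolutional tumor-identification network.

A VGG-style encoder downsamples the 288x288 input four times to an
18x18 feature map.  Two parallel branches read that map: a plain 3x3
convolution and a 3x3 atrous convolution with dilation 2 (effective
receptive field 5x5) whose output passes through a 1x1 transitional
convolution with 512 filters to balance the channel counts; the two
branches are concatenated, fused, and reduced to a one-channel score.
The decoder follows the FCN-16s pattern: one learnable 2x upsampling of
the score fused with a skip from the penultimate pooling stage, then a
bilinear restoration to the input resolution and a per-pixel sigmoid.

Training minimizes the soft Dice loss with SGD + momentum; inputs are
standardized, and the identification augmentation policy is redrawn
every epoch.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .augment import AugPolicy, augment_roi_sample, standardize
from .nn import Tensor

__all__ = ["RoiNetConfig", "TrainConfig", "RoiNet", "build_roi_net",
           "roi_forward", "dice_loss", "train_roi_net"]


@dataclasses.dataclass
class RoiNetConfig:
    input_size: int = 288
    backbone_downsamplings: int = 4
    convs_per_block: int = 2
    base_filters: int = 64
    atrous_kernel: int = 3
    atrous_dilation: int = 2
    transitional_kernel: int = 1
    transitional_filters: int = 512
    batch_norm: bool = True
    init_mode: str = "gaussian_random"  # "gaussian_random" | "vgg_pretrained"
    seed: int = 0

    def __post_init__(self):
        if self.input_size % (2 ** self.backbone_downsamplings) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^{self.backbone_downsamplings}")
        if self.init_mode not in ("gaussian_random", "vgg_pretrained"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def deep_feature_size(self) -> int:
        return self.input_size // (2 ** self.backbone_downsamplings)


@dataclasses.dataclass
class TrainConfig:
    """SGD recipe shared by both networks.

    Reference defaults: minibatch 16, momentum 0.9; learning rate 1e-4
    for the identification net and 1e-3 with a 0.9 per-epoch decay for
    the grading net.  ``lr_decay = 1`` disables the schedule.
    """

    batch_size: int = 16
    learning_rate: float = 1e-4
    momentum: float = 0.9
    lr_decay: float = 1.0
    epochs: int = 10
    seed: int = 0
    weight_decay: float = 0.0
    augment: bool = True

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0 or self.lr_decay <= 0:
            raise ValueError("rates must be positive")


class _EncoderBlock(nn.Module):
    def __init__(self, c_in, c_out, n_convs, rng, batch_norm):
        self.convs = [nn.Conv2d(c_in if i == 0 else c_out, c_out, 3, rng)
                      for i in range(n_convs)]
        self.bns = [nn.BatchNorm(c_out) for _ in range(n_convs)] if batch_norm else []

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if self.bns:
                x = self.bns[i](x, train)
            x = nn.relu(x)
        return nn.maxpool2(x)


class RoiNet(nn.Module):
    def __init__(self, cfg: RoiNetConfig):
        if cfg.init_mode == "vgg_pretrained":
            raise NotImplementedError(
                "vgg_pretrained init requires an external weights file; "
                "use init_mode='gaussian_random'")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        channels = [min(f * 2 ** b, 8 * f) for b in range(cfg.backbone_downsamplings)]
        self.blocks = []
        c_in = 1
        for c_out in channels:
            self.blocks.append(_EncoderBlock(c_in, c_out, cfg.convs_per_block,
                                             rng, cfg.batch_norm))
            c_in = c_out
        deep = channels[-1]
        self.top_conv = nn.Conv2d(deep, deep, 3, rng)
        self.atrous_conv = nn.Conv2d(deep, deep, cfg.atrous_kernel, rng,
                                     dilation=cfg.atrous_dilation)
        self.transitional = nn.Conv2d(deep, cfg.transitional_filters,
                                      cfg.transitional_kernel, rng)
        self.fuse_conv = nn.Conv2d(deep + cfg.transitional_filters, deep, 3, rng)
        self.score_conv = nn.Conv2d(deep, 1, 1, rng)
        self.up_conv = nn.Conv2d(1, 1, 3, rng)  # learnable 2x upsampling tail
        self.skip_conv = nn.Conv2d(channels[-2], 1, 1, rng)
        if cfg.batch_norm:
            self.top_bn = nn.BatchNorm(deep)
            self.atrous_bn = nn.BatchNorm(deep)
            self.trans_bn = nn.BatchNorm(cfg.transitional_filters)
            self.fuse_bn = nn.BatchNorm(deep)

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        """Input (N, H, W) or (N, 1, H, W) standardized floats -> (N,1,H,W) probs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(f"expected {self.cfg.input_size}px input, got {x.shape}")
        t = Tensor(x)
        skips = []
        for block in self.blocks:
            t = block(t, train)
            skips.append(t)
        bn = self.cfg.batch_norm
        top = nn.relu(self.top_bn(self.top_conv(t), train) if bn else self.top_conv(t))
        atr = nn.relu(self.atrous_bn(self.atrous_conv(t), train) if bn else self.atrous_conv(t))
        trans = nn.relu(self.trans_bn(self.transitional(atr), train) if bn else self.transitional(atr))
        cat = nn.concat([top, trans], axis=1)
        fuse = nn.relu(self.fuse_bn(self.fuse_conv(cat), train) if bn else self.fuse_conv(cat))
        score = self.score_conv(fuse)
        up = self.up_conv(nn.nearest_upsample2(score))
        skip = self.skip_conv(skips[-2])
        fused = nn.add(up, skip)
        full = nn.bilinear_resize(fused, self.cfg.input_size, self.cfg.input_size)
        return nn.sigmoid(full)

    def fingerprint(self) -> dict:
        """Architecture summary, stable under reseeding (JSON-serializable)."""
        n_conv = sum(len(b.convs) for b in self.blocks) + 6
        n_params = sum(p.data.size for p in self.parameters())
        return {
            "model": "roi_cnn",
            "input_size": self.cfg.input_size,
            "deep_feature_size": self.cfg.deep_feature_size,
            "n_conv_layers": n_conv,
            "n_parameters": int(n_params),
            "atrous": {"kernel": self.cfg.atrous_kernel,
                       "dilation": self.cfg.atrous_dilation,
                       "effective_kernel": self.atrous_conv.effective_kernel},
            "transitional": {"kernel": self.cfg.transitional_kernel,
                             "filters": self.cfg.transitional_filters},
            "batch_norm": self.cfg.batch_norm,
        }

    def save_fingerprint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.fingerprint(), fh, indent=2)


def build_roi_net(cfg: RoiNetConfig | None = None) -> RoiNet:
    return RoiNet(cfg or RoiNetConfig())


def roi_forward(net: RoiNet, image: np.ndarray, pre_standardize: bool = True) -> np.ndarray:
    """Predict the tumor-possibility map of one image (eval mode)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("roi_forward takes a single 2-D image")
    if pre_standardize:
        image = standardize(image)
    out = net.forward(image[None], train=False)
    return np.asarray(out.data[0, 0], dtype=np.float64)


def dice_loss(pred: np.ndarray, gt: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss 1 - (2 sum(p*g) + eps) / (sum p + sum g + eps).

    Array-level counterpart of the training loss; 0 for perfect
    agreement (and for the doubly-empty case), -> 1 for disjoint masks.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    inter = float((pred * gt).sum())
    sums = float(pred.sum() + gt.sum())
    return 1.0 - (2.0 * inter + eps) / (sums + eps)


def _as_arrays(data):
    """Accept (images, masks) arrays or a manifest DataFrame with paths."""
    if isinstance(data, tuple):
        images, masks = data
        return [np.asarray(i, float) for i in images], [np.asarray(m, bool) for m in masks]
    from . import io as egio
    images, masks = [], []
    for _, row in data.iterrows():
        images.append(egio.read_image(row["image"]))
        masks.append(egio.read_mask(row["mask"]))
    return images, masks


def train_roi_net(net: RoiNet, data, tcfg: TrainConfig,
                  policy: AugPolicy | None = None) -> list[float]:
    """SGD training with per-epoch augmentation; returns per-epoch mean loss."""
    images, masks = _as_arrays(data)
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    policy = policy or AugPolicy(kind="roi")
    opt = nn.SGD(net.parameters(), lr=tcfg.learning_rate,
                 momentum=tcfg.momentum, weight_decay=tcfg.weight_decay)
    history: list[float] = []
    n = len(images)
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb, yb = [], []
            for i in idx:
                if tcfg.augment:
                    im, mk = augment_roi_sample(images[i], masks[i], rng, policy)
                else:
                    im, mk = standardize(images[i]), masks[i]
                xb.append(im)
                yb.append(mk)
            pred = net.forward(np.stack(xb).astype(np.float32), train=True)
            loss = nn.dice_loss_value(pred, np.stack(yb)[:, None])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite Dice loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        opt.lr *= tcfg.lr_decay
    return history
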
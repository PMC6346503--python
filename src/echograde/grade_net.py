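"""G-CNN: the 5-category grading network.

Nine blocks.  Blocks 1-4 form the encode path (two 3x3 convolutions and
one 2x2/stride-2 max pool each, channel count doubling per block);
Block 5 holds three 3x3 convolutions at the deepest resolution; Blocks
6-9 form the concatenate path, each a concatenation layer followed by
one 3x3 convolution, fusing the running features with a skip from the
paired encode block (default pairing 4-6, 3-7, 2-8, 1-9).  Because the
concatenate path runs at the deepest resolution while encode blocks 1-3
produce larger maps, each of those blocks feeds its skip through a side
branch of one 3x3 convolution followed by 2x2/stride-2 max pooling down
to the matching size.  The network has exactly 18 convolution layers;
batch normalization sits on the top convolution of every block and on
the first two of the three fully connected layers (4096, 1024, 5), and
a softmax head emits the 5 category probabilities.

Training: SGD with momentum on categorical cross entropy, L2 weight
decay, learning rate decayed by a constant factor per epoch, and the
fourfold offline grading augmentation.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .augment import AugPolicy, augment_grade_sample, standardize
from .metrics import GRADE_INDEX, GRADE_VALUES
from .nn import Tensor
from .roi_net import TrainConfig

__all__ = ["GNetConfig", "GCnn", "build_g_cnn", "g_forward",
           "cross_entropy_loss", "predict_category", "train_g_cnn"]

_DEFAULT_PAIRING = ((1, 9), (2, 8), (3, 7), (4, 6))


@dataclasses.dataclass
class GNetConfig:
    input_size: int = 288
    base_filters: int = 32
    fc_sizes: tuple[int, int, int] = (4096, 1024, 5)
    l2_weight: float = 1e-4
    pairing: tuple = _DEFAULT_PAIRING
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")
        if self.fc_sizes[-1] != len(GRADE_VALUES):
            raise ValueError("final FC layer must have 5 neurons")
        encs = sorted(e for e, _ in self.pairing)
        cats = sorted(c for _, c in self.pairing)
        if encs != [1, 2, 3, 4] or cats != [6, 7, 8, 9]:
            raise ValueError("pairing must match encode blocks 1-4 to concat blocks 6-9")


class _SideBranch(nn.Module):
    """One 3x3 conv + repeated 2x2/s2 pooling down to the target size."""

    def __init__(self, channels, n_pools, rng):
        self.conv = nn.Conv2d(channels, channels, 3, rng)
        self.n_pools = n_pools

    def __call__(self, x: Tensor) -> Tensor:
        x = nn.relu(self.conv(x))
        for _ in range(self.n_pools):
            x = nn.maxpool2(x)
        return x


class GCnn(nn.Module):
    def __init__(self, cfg: GNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        enc_channels = [f, 2 * f, 4 * f, 8 * f]
        self.enc_convs = []   # 4 blocks x 2 convs
        self.enc_bns = []     # BN on the top conv of each block
        c_in = 1
        for c in enc_channels:
            self.enc_convs.append([nn.Conv2d(c_in, c, 3, rng), nn.Conv2d(c, c, 3, rng)])
            self.enc_bns.append(nn.BatchNorm(c))
            c_in = c
        deep = enc_channels[-1]
        self.block5_convs = [nn.Conv2d(deep, deep, 3, rng) for _ in range(3)]
        self.block5_bn = nn.BatchNorm(deep)
        # concat path: order blocks 6..9; partner sizes decide side branches
        self.partner_of = {c: e for e, c in cfg.pairing}
        deep_size = cfg.input_size // 16
        enc_sizes = [cfg.input_size // 2 ** (b + 1) for b in range(4)]  # post-pool
        self.side_branches = {}
        self.cat_convs = []
        self.cat_bns = []
        c_prev = deep
        for cblock in (6, 7, 8, 9):
            e = self.partner_of[cblock]
            e_size = enc_sizes[e - 1]
            e_ch = enc_channels[e - 1]
            if e_size != deep_size:
                ratio = e_size // deep_size
                if ratio * deep_size != e_size or ratio & (ratio - 1):
                    raise ValueError(
                        f"concatenation size mismatch: encode block {e} at "
                        f"{e_size}px cannot meet concat block {cblock} at {deep_size}px")
                self.side_branches[e] = _SideBranch(e_ch, ratio.bit_length() - 1, rng)
            out_ch = e_ch
            self.cat_convs.append(nn.Conv2d(c_prev + e_ch, out_ch, 3, rng))
            self.cat_bns.append(nn.BatchNorm(out_ch))
            c_prev = out_ch
        self._sides = list(self.side_branches.values())  # registered for parameters()
        flat = deep_size * deep_size * c_prev
        sizes = [flat, *cfg.fc_sizes]
        self.fcs = [nn.Dense(sizes[i], sizes[i + 1], rng) for i in range(3)]
        self.fc_bns = [nn.BatchNorm(cfg.fc_sizes[0]), nn.BatchNorm(cfg.fc_sizes[1])]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> Tensor:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(f"expected {self.cfg.input_size}px input, got {x.shape}")
        t = Tensor(x)
        enc_feats = []
        for b, convs in enumerate(self.enc_convs):
            t = nn.relu(convs[0](t))
            t = nn.relu(self.enc_bns[b](convs[1](t), train))
            t = nn.maxpool2(t)
            enc_feats.append(t)
        for i, conv in enumerate(self.block5_convs):
            h = conv(t)
            if i == len(self.block5_convs) - 1:
                h = self.block5_bn(h, train)
            t = nn.relu(h)
        for ci, cblock in enumerate((6, 7, 8, 9)):
            e = self.partner_of[cblock]
            skip = enc_feats[e - 1]
            if e in self.side_branches:
                skip = self.side_branches[e](skip)
            if skip.shape[2:] != t.shape[2:]:
                raise ValueError(
                    f"concatenation mismatch at block {cblock}: {skip.shape} vs {t.shape}")
            t = nn.concat([t, skip], axis=1)
            t = nn.relu(self.cat_bns[ci](self.cat_convs[ci](t), train))
        t = nn.flatten(t)
        t = nn.relu(self.fc_bns[0](self.fcs[0](t), train))
        t = nn.relu(self.fc_bns[1](self.fcs[1](t), train))
        return self.fcs[2](t)

    def forward_probs(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return nn.softmax(self.forward_logits(x, train).data)

    def fingerprint(self) -> dict:
        n_conv = (sum(len(c) for c in self.enc_convs) + len(self.block5_convs)
                  + len(self.cat_convs) + len(self.side_branches))
        return {
            "model": "g_cnn",
            "input_size": self.cfg.input_size,
            "n_blocks": 9,
            "n_conv_layers": n_conv,
            "conv_kernel": 3,
            "pool": {"size": 2, "stride": 2},
            "fc_sizes": list(self.cfg.fc_sizes),
            "pairing": [list(p) for p in self.cfg.pairing],
            "n_parameters": int(sum(p.data.size for p in self.parameters())),
        }

    def save_fingerprint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.fingerprint(), fh, indent=2)


def build_g_cnn(cfg: GNetConfig | None = None) -> GCnn:
    return GCnn(cfg or GNetConfig())


def g_forward(net: GCnn, roi_image: np.ndarray, pre_standardize: bool = True) -> np.ndarray:
    """Grade one ROI image; returns the 5 softmax probabilities."""
    roi_image = np.asarray(roi_image, dtype=np.float64)
    if roi_image.ndim != 2:
        raise ValueError("g_forward takes a single 2-D image")
    if pre_standardize:
        roi_image = standardize(roi_image)
    return g_forward_batch(net, roi_image[None])[0]


def g_forward_batch(net: GCnn, images: np.ndarray) -> np.ndarray:
    probs = net.forward_probs(np.asarray(images, dtype=np.float32), train=False)
    return np.asarray(probs, dtype=np.float64)


def cross_entropy_loss(probs: np.ndarray, labels, clip: float = 1e-12) -> float:
    """Mean categorical cross entropy -log p(true class) over a batch."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    idx = np.asarray([GRADE_INDEX[str(l)] if not isinstance(l, (int, np.integer)) else int(l)
                      for l in np.atleast_1d(labels)])
    if probs.shape[0] != idx.shape[0]:
        raise ValueError("probs/labels length mismatch")
    p = np.clip(probs[np.arange(len(idx)), idx], clip, 1.0)
    return float(-np.log(p).mean())


def predict_category(probs: np.ndarray) -> str:
    """Highest-probability grade; exact ties resolve to the lowest index."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (len(GRADE_VALUES),):
        raise ValueError(f"expected {len(GRADE_VALUES)} probabilities")
    return GRADE_VALUES[int(np.argmax(probs))]


def train_g_cnn(net: GCnn, data, tcfg: TrainConfig,
                policy: AugPolicy | None = None) -> list[float]:
    """Train on (images, labels); returns per-epoch mean cross entropy.

    The grading augmentation expands the dataset fourfold offline before
    the first epoch (disable with ``tcfg.augment = False``).  The
    learning rate is multiplied by ``tcfg.lr_decay`` after every epoch.
    """
    images, labels = data
    labels = [str(l) for l in labels]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    rng = np.random.default_rng(tcfg.seed)
    if tcfg.augment:
        policy = policy or AugPolicy(kind="grade", max_shift=max(2, net.cfg.input_size // 15))
        aug_imgs, aug_labels = [], []
        for img, lab in zip(images, labels):
            for a_img, a_lab in augment_grade_sample(img, lab, rng, policy):
                aug_imgs.append(a_img)
                aug_labels.append(a_lab)
        images, labels = aug_imgs, aug_labels
    x = np.stack([standardize(im) for im in images]).astype(np.float32)
    y = np.asarray([GRADE_INDEX[l] for l in labels])
    opt = nn.SGD(net.parameters(), lr=tcfg.learning_rate, momentum=tcfg.momentum,
                 weight_decay=tcfg.weight_decay if tcfg.weight_decay else net.cfg.l2_weight)
    history: list[float] = []
    n = len(x)
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            logits = net.forward_logits(x[idx], train=True)
            loss = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite cross entropy at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        opt.lr *= tcfg.lr_decay
    return history
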
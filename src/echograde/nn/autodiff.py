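"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd style, with exactly the
operations the identification and grading networks need: dilated 2-D
convolution, 2x2 max pooling, dense layers, batch normalization,
channel concatenation, nearest/bilinear upsampling and the two loss
heads (soft Dice, softmax cross entropy).  Convolutions use a
tap-accumulation scheme (one BLAS contraction per kernel element)
rather than im2col, which keeps memory flat at the image sizes used
here.

All operations are deterministic; dtype follows the input arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "concat",
    "conv2d",
    "relu",
    "sigmoid",
    "maxpool2",
    "dense",
    "batchnorm",
    "nearest_upsample2",
    "bilinear_resize",
    "flatten",
    "dice_loss_value",
    "softmax_cross_entropy",
    "softmax",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray.

    ``requires_grad`` marks trainable leaves; intermediate nodes carry a
    backward closure recorded by the op that produced them.
    """

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad", "name")

    def __init__(self, data, parents=(), requires_grad=False, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self._backward = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) node through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(g):
        a._accumulate(g)
        b._accumulate(g)

    out._backward = _bw
    return out


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, gs in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(gs)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), parents=(x,))

    def _bw(g):
        x._accumulate(g * mask)

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def _bw(g):
        x._accumulate(g * s * (1.0 - s))

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 convolution, NCHW layout.

    ``w`` has shape (C_out, C_in, k, k) with k odd; the effective kernel
    extent is k + (k-1)(dilation-1).
    """
    n, c, h, wd = x.data.shape
    co, ci, k, k2 = w.data.shape
    if ci != c or k != k2:
        raise ValueError(f"kernel {w.data.shape} incompatible with input {x.data.shape}")
    d = dilation
    pad = d * (k // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_data = np.zeros((n, co, h, wd), dtype=x.data.dtype)
    # one contraction per kernel tap; cached slices reused in backward
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * d : i * d + h, j * d : j * d + wd]
            # (co,ci) x (n,ci,h,w) -> (co,n,h,w)
            out_data += np.moveaxis(
                np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1])), 0, 1
            )
    out_data += b.data.reshape(1, co, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def _bw(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d : i * d + h, j * d : j * d + wd]
                gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                # (n,co,h,w) x (co,ci) -> (n,h,w,ci)
                gx = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                gxp[:, :, i * d : i * d + h, j * d : j * d + wd] += np.moveaxis(
                    gx, 3, 1
                )
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 2, 3)))
        if pad:
            x._accumulate(gxp[:, :, pad:-pad, pad:-pad])
        else:
            x._accumulate(gxp)

    out._backward = _bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    windows = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = windows.argmax(axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def _bw(g):
        gwin = np.zeros_like(windows)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = (
            gwin.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    out._backward = _bw
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    out = Tensor(x.data @ w.data + b.data, parents=(x, w, b))

    def _bw(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)
        b._accumulate(g.sum(axis=0))

    out._backward = _bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running, train: bool, momentum=0.9, eps=1e-5) -> Tensor:
    """Batch normalization over (N,) or (N,H,W) per channel.

    ``running`` is a dict with mutable "mean"/"var" arrays updated in
    train mode and used verbatim in eval mode.
    """
    nd = x.data.ndim
    axes = (0,) if nd == 2 else (0, 2, 3)
    shape = (1, -1) if nd == 2 else (1, -1, 1, 1)
    if train:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] *= momentum
        running["mean"] += (1 - momentum) * mu
        running["var"] *= momentum
        running["var"] += (1 - momentum) * var
    else:
        mu = running["mean"]
        var = running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = Tensor(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape), parents=(x, gamma, beta))
    m = x.data.size // x.data.shape[1]

    def _bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gs = g * gamma.data.reshape(shape)
        if train:
            gx = (
                gs
                - gs.mean(axis=axes).reshape(shape)
                - xhat * (gs * xhat).mean(axis=axes).reshape(shape)
            ) * inv.reshape(shape)
        else:
            gx = gs * inv.reshape(shape)
        x._accumulate(gx)

    del m
    out._backward = _bw
    return out


def nearest_upsample2(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(out_data, parents=(x,))
    n, c, h, w = x.data.shape

    def _bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix, half-pixel-centre convention."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[o, lo_c] += 1.0 - t
        a[o, hi_c] += t
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize as an exact linear operator (so the adjoint is exact)."""
    ah = _interp_matrix(out_h, x.data.shape[2], x.data.dtype)
    aw = _interp_matrix(out_w, x.data.shape[3], x.data.dtype)
    t = np.tensordot(x.data, ah, axes=([2], [1]))  # (n,c,in_w,out_h)
    out_data = np.tensordot(t, aw, axes=([2], [1]))  # (n,c,out_h,out_w)
    out = Tensor(np.ascontiguousarray(out_data), parents=(x,))

    def _bw(g):
        tg = np.tensordot(g, ah, axes=([2], [0]))  # (n,c,out_w,in_h)
        gx = np.tensordot(tg, aw, axes=([2], [0]))  # (n,c,in_h,in_w)
        x._accumulate(np.ascontiguousarray(gx))

    out._backward = _bw
    return out


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    orig = x.data.shape
    out = Tensor(x.data.reshape(n, -1), parents=(x,))

    def _bw(g):
        x._accumulate(g.reshape(orig))

    out._backward = _bw
    return out


def dice_loss_value(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss, averaged over the batch.

    ``pred`` holds probabilities in [0,1] with shape (N, 1, H, W) or
    (N, H, W); ``target`` is a 0/1 array of the same shape.  Perfect
    agreement gives ~0, disjoint/empty prediction gives ~1.  Both empty
    gives 0 (vacuous agreement, via the eps terms).
    """
    p = pred.data.reshape(pred.data.shape[0], -1)
    t = np.asarray(target, dtype=p.dtype).reshape(p.shape[0], -1)
    inter = (p * t).sum(axis=1)
    sums = p.sum(axis=1) + t.sum(axis=1)
    dice = (2.0 * inter + eps) / (sums + eps)
    out = Tensor(np.asarray((1.0 - dice).mean(), dtype=p.dtype), parents=(pred,))
    n = p.shape[0]

    def _bw(g):
        # d(1-dice_i)/dp = -(2 t (sums+eps) - (2 inter+eps)) / (sums+eps)^2
        denom = (sums + eps)[:, None]
        gp = -(2.0 * t * denom - (2.0 * inter + eps)[:, None]) / denom**2
        pred._accumulate((g * gp / n).reshape(pred.data.shape))

    out._backward = _bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross entropy from logits; labels are class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    idx = np.asarray(labels)
    loss = -logp[np.arange(n), idx].mean()
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,))
    probs = np.exp(logp)

    def _bw(g):
        gl = probs.copy()
        gl[np.arange(n), idx] -= 1.0
        logits._accumulate(g * gl / n)

    out._backward = _bw
    return out
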
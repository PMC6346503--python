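"""Parameterized layers and the SGD optimizer built on the autodiff tape."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Dense", "BatchNorm", "SGD"]


class Module:
    """Base class: tracks child modules and exposes trainable parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and BN running stats."""
        out: dict[str, np.ndarray] = {}

        def walk(mod, prefix):
            for k, v in vars(mod).items():
                key = f"{prefix}{k}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v.data
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                elif isinstance(v, dict) and set(v) == {"mean", "var"}:
                    out[key + ".mean"] = v["mean"]
                    out[key + ".var"] = v["var"]

        walk(self, "")
        return out

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as archive:
            state = self.state_arrays()
            missing = set(state) - set(archive.files)
            if missing:
                raise ValueError(f"checkpoint missing arrays: {sorted(missing)}")
            for k, arr in state.items():
                loaded = archive[k]
                if loaded.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {k}: {loaded.shape} vs {arr.shape}")
                arr[...] = loaded


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Conv2d(Module):
    """Same-padded stride-1 convolution with optional dilation.

    Weights are Gaussian (He-scaled) draws from the supplied generator,
    matching the "Gaussian randomizer" initialization of the reference
    training recipe.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, dtype=np.float32):
        std = _he_std(c_in * kernel * kernel)
        self.w = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)).astype(dtype),
                        requires_grad=True, name="conv.w")
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True, name="conv.b")
        self.dilation = dilation
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, dilation=self.dilation)

    @property
    def effective_kernel(self) -> int:
        """Receptive-field extent k + (k-1)(d-1) of a single application."""
        return self.kernel + (self.kernel - 1) * (self.dilation - 1)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Tensor(rng.normal(0.0, _he_std(n_in), (n_in, n_out)).astype(dtype),
                        requires_grad=True, name="dense.w")
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True, name="dense.b")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.dense(x, self.w, self.b)


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.9, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True, name="bn.gamma")
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True, name="bn.beta")
        self.running = {"mean": np.zeros(channels, dtype=np.float64),
                        "var": np.ones(channels, dtype=np.float64)}
        self.momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return ad.batchnorm(x, self.gamma, self.beta, self.running, train,
                            momentum=self.momentum)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
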
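"""Network building blocks: convolution, batch norm, PReLU, Adam.

Parameters are created in the network's configured precision and
initialised from a caller-supplied ``numpy.random.Generator`` so that
construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .engine import Tensor, batchnorm_train, conv_nd, prelu

__all__ = ["Module", "Conv", "BatchNorm", "PReLU", "Sequential", "Adam"]


class Module:
    """Base class with recursive parameter collection."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _all_modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v._all_modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item._all_modules()

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus batch-norm running statistics, in traversal order."""
        arrays = [p.data for p in self.parameters()]
        for m in self._all_modules():
            if isinstance(m, BatchNorm):
                arrays += [m.running_mean, m.running_var]
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        bns = [m for m in self._all_modules() if isinstance(m, BatchNorm)]
        if len(arrays) != len(params) + 2 * len(bns):
            raise ValueError("checkpoint array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()
        rest = arrays[len(params):]
        for m, mean, var in zip(bns, rest[0::2], rest[1::2]):
            m.running_mean = np.asarray(mean, dtype=m.running_mean.dtype).copy()
            m.running_var = np.asarray(var, dtype=m.running_var.dtype).copy()


class Conv(Module):
    """'Same' convolution, stride 1.  kernel is a tuple, e.g. (3,3,1) or (3,3)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, ...],
                 rng: np.random.Generator, dtype=np.float64):
        fan_in = in_ch * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)                   # He initialisation
        w = rng.normal(0.0, scale, (out_ch, in_ch) + tuple(kernel)).astype(dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias)


class BatchNorm(Module):
    """Per-channel batch normalisation over batch and spatial axes."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(n_ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            return out
        shape = (1, -1) + (1,) * (x.ndim - 2)
        mu = self.running_mean.reshape(shape)
        sd = np.sqrt(self.running_var + self.eps).reshape(shape)
        xn = (x - mu) * (1.0 / sd)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class PReLU(Module):
    """Per-channel parametric ReLU: y = max(x,0) + a*min(x,0)."""

    def __init__(self, n_ch: int, init: float = 0.25, dtype=np.float64):
        self.alpha = Tensor(np.full(n_ch, init, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.alpha)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Adam:
    """Adam optimiser (defaults match the training protocol: lr 1e-4,
    betas (0.9, 0.999))."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
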
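"""Neural-network building blocks on the numpy autodiff tape.

Layers mirror the familiar torch.nn surface (``Conv2d``, ``BatchNorm2d``,
``Linear``, ``LayerNorm``, ``Sequential`` ...) closely enough that the
detection architecture reads like its reference implementations.  Every layer
that performs dense arithmetic reports multiply–accumulate counts to the
profiler hook (see :mod:`phrfdet.profiling`); normalisation and activations
are free under the profiling convention used across the YOLO/RT-DETR
ecosystem.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity", "Conv2d", "Linear",
    "BatchNorm2d", "LayerNorm", "SiLU", "ReLU", "GELU", "MaxPool2d",
    "AvgPool2d", "UpsampleNearest2d", "Embedding", "ConvNormAct", "Dropout",
]

# ---------------------------------------------------------------------------
# MAC counting hook.  ``phrfdet.profiling`` installs a counter here while a
# profiled forward pass runs.
_MAC_COUNTER = None


def add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


def set_mac_counter(counter) -> None:
    global _MAC_COUNTER
    _MAC_COUNTER = counter


class Module:
    """Base class: parameter registry, train/eval mode, recursion."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        """Exact trainable-weight count (the framework side of the Eq-10 check)."""
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = ""):
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, sd: dict, prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.asarray(sd[prefix + name], dtype=np.float32)
        for name in list(self._buffers):
            self._buffers[name] = np.asarray(sd[prefix + name])
            object.__setattr__(self, name, self._buffers[name])
        for name, m in self._modules.items():
            m.load_state_dict(sd, prefix + name + ".")

    def __call__(self, *a, **k):
        return self.forward(*a, **k)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            self._modules[str(i)] = l

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, *a):  # pragma: no cover - containers are not called
        raise RuntimeError("ModuleList is not callable")


class Identity(Module):
    def forward(self, x):
        return x


class Dropout(Module):
    """Inverted dropout; inert in eval mode and at p=0."""

    def __init__(self, p: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


def _kaiming(shape, fan_in, rng):
    bound = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * bound).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the weight-initialisation stream (used by model builders)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """2-D convolution via im2col + GEMM, with grouping.

    Weight layout ``(C_out, C_in/groups, k, k)``; same-padding conventions are
    the caller's responsibility (``padding`` is symmetric).
    """

    def __init__(self, c_in, c_out, k, stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = c_in // groups * k * k
        self.weight = Parameter(_kaiming((c_out, c_in // groups, k, k), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    # -- im2col helpers -------------------------------------------------------
    def _cols(self, xd: np.ndarray):
        N, C, H, W = xd.shape
        k, s = self.k, self.stride
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        sN, sC, sH, sW = xd.strides
        shape = (N, C, Ho, Wo, k, k)
        strides = (sN, sC, sH * s, sW * s, sH, sW)
        patches = np.lib.stride_tricks.as_strided(xd, shape, strides)
        return patches, Ho, Wo

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = x.pad2d(self.padding, self.padding)
        xd = x.data
        N, C, H, W = xd.shape
        k, s, g = self.k, self.stride, self.groups
        patches, Ho, Wo = self._cols(xd)
        # (N, Ho, Wo, C*k*k)
        cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        w = self.weight.data.reshape(self.c_out, -1)  # (C_out, C_in/g*k*k)
        if g == 1:
            out = cols @ w.T
        else:
            cg = C // g
            og = self.c_out // g
            cols_g = cols.reshape(N * Ho * Wo, g, cg * k * k)
            w_g = self.weight.data.reshape(g, og, cg * k * k)
            out = np.einsum("ngc,goc->ngo", cols_g, w_g).reshape(N * Ho * Wo, self.c_out)
        if self.bias is not None:
            out = out + self.bias.data
        out = out.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)
        add_macs(N * Ho * Wo * self.c_out * (C // g) * k * k)

        parents = [p for p in (x, self.weight, self.bias) if p is not None]

        def backward(gout):
            # gout: (N, C_out, Ho, Wo)
            gflat = gout.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
            if self.bias is not None and self.bias.requires_grad:
                self.bias._accum(gflat.sum(axis=0))
            if g == 1:
                if self.weight.requires_grad:
                    self.weight._accum((gflat.T @ cols).reshape(self.weight.data.shape))
                gcols = gflat @ w
            else:
                cg = C // g
                og = self.c_out // g
                gflat_g = gflat.reshape(N * Ho * Wo, g, og)
                cols_g = cols.reshape(N * Ho * Wo, g, cg * k * k)
                if self.weight.requires_grad:
                    gw = np.einsum("ngo,ngc->goc", gflat_g, cols_g)
                    self.weight._accum(gw.reshape(self.weight.data.shape))
                w_g = self.weight.data.reshape(g, og, cg * k * k)
                gcols = np.einsum("ngo,goc->ngc", gflat_g, w_g).reshape(
                    N * Ho * Wo, C * k * k
                )
            if x.requires_grad:
                gx = np.zeros((N, C, H, W), dtype=np.float32)
                gp = gcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
                for i in range(k):
                    for j in range(k):
                        gx[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += gp[..., i, j]
                x._accum(gx)

        out_t = Tensor._from_op(out, tuple(parents), backward)
        return out_t


class Linear(Module):
    def __init__(self, n_in, n_out, bias=True):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        bound = math.sqrt(1.0 / n_in)
        self.weight = Parameter(
            (_INIT_RNG.uniform(-bound, bound, (n_out, n_in))).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ _transposed_view(self.weight)
        if self.bias is not None:
            out = out + self.bias
        add_macs(int(np.prod(x.shape[:-1])) * self.n_in * self.n_out)
        return out


def _transposed_view(p: Parameter) -> Tensor:
    """A Tensor view of ``p.T`` whose gradient accumulates into ``p``."""
    out = Tensor(p.data.T)

    def backward(g):
        if p.requires_grad:
            p._accum(g.T)

    if p.requires_grad:
        out.requires_grad = True
        out._parents = (p,)
        out._backward = backward
    return out


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self._buffers["running_mean"] = self.running_mean
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
            self._buffers["running_var"] = self.running_var
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.d, self.eps = d, eps
        self.weight = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight + self.bias


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    """tanh-free exact GELU via the error function."""

    def forward(self, x):
        from scipy.special import erf

        cdf = 0.5 * (1.0 + erf(x.data / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x.data**2) / math.sqrt(2 * math.pi)

        def backward(g):
            if x.requires_grad:
                x._accum(g * (cdf + x.data * pdf))

        return Tensor._from_op(x.data * cdf, (x,), backward)


_ACTIVATIONS = {"silu": SiLU, "relu": ReLU, "gelu": GELU, "identity": Identity}


def make_activation(name: str) -> Module:
    try:
        return _ACTIVATIONS[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


class ConvNormAct(Module):
    """Conv → BatchNorm → activation; bias off under the norm (it is redundant
    and would distort the closed-form parameter accounting)."""

    def __init__(self, c_in, c_out, k=1, stride=1, padding=None, groups=1,
                 norm=True, act="silu"):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.conv = Conv2d(c_in, c_out, k, stride, padding, groups, bias=not norm)
        self.norm = BatchNorm2d(c_out) if norm else Identity()
        self.act = make_activation(act)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class MaxPool2d(Module):
    def __init__(self, k, stride, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            spec = [(0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2]
            xd = np.pad(x.data, spec, constant_values=-np.inf)
        else:
            xd = x.data
        N, C, H, W = xd.shape
        k, s = self.k, self.stride
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        sN, sC, sH, sW = xd.strides
        patches = np.lib.stride_tricks.as_strided(
            xd, (N, C, Ho, Wo, k, k), (sN, sC, sH * s, sW * s, sH, sW)
        ).reshape(N, C, Ho, Wo, k * k)
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not x.requires_grad:
                return
            gx = np.zeros(xd.shape, dtype=np.float32)
            ii, jj = np.unravel_index(idx, (k, k))
            n_, c_, ho_, wo_ = np.meshgrid(
                np.arange(N), np.arange(C), np.arange(Ho), np.arange(Wo), indexing="ij"
            )
            np.add.at(gx, (n_, c_, ho_ * s + ii, wo_ * s + jj), g)
            p = self.padding
            x._accum(gx[:, :, p : p + x.shape[2], p : p + x.shape[3]] if p else gx)

        return Tensor._from_op(out, (x,), backward)


class AvgPool2d(Module):
    """Non-overlapping average pooling (k == stride), NCHW."""

    def __init__(self, k):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        k = self.k
        if k == 1:
            return x
        N, C, H, W = x.shape
        if H % k or W % k:
            raise ValueError(f"AvgPool2d: ({H},{W}) not divisible by {k}")
        y = x.reshape(N, C, H // k, k, W // k, k)
        return y.mean(axis=5).mean(axis=3)


class UpsampleNearest2d(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        f = self.scale
        N, C, H, W = x.shape
        out_data = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

        def backward(g):
            if x.requires_grad:
                x._accum(
                    g.reshape(N, C, H, f, W, f).sum(axis=(3, 5))
                )

        return Tensor._from_op(out_data, (x,), backward)


class Embedding(Module):
    def __init__(self, n, d):
        super().__init__()
        self.weight = Parameter(
            (_INIT_RNG.standard_normal((n, d)) * 0.02).astype(np.float32)
        )

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx)]
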
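"""Neural-network layers on top of the autodiff tensor.

Activations flow through the layers in channels-last (N, H, W, C) layout:
with channels contiguous, a stride-1 convolution is one full-image
(N*H*W, Cin) x (Cin, Cout) matrix product per kernel offset with *no*
im2col copies — the offset shift becomes a strided slice of the product.
The network modules convert from the public channels-first (N, C, H, W)
convention at their boundaries.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, make_node, leaky_relu, matmul, relu, sigmoid


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_tensors(self):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield name, value, True
            elif isinstance(value, Tensor):
                yield name, value, False  # buffer (e.g. running stats)

    def parameters(self):
        for name, value, is_param in self._own_tensors():
            if is_param:
                yield value
        for _, child in self._children():
            yield from child.parameters()

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, value, _ in self._own_tensors():
            out[prefix + name] = value.data.copy()
        for cname, child in self._children():
            out.update(child.state_dict(prefix + cname + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for name, value, _ in self._own_tensors():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing key in state dict: {key}")
            arr = np.asarray(state[key], dtype=value.data.dtype)
            if arr.shape != value.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {arr.shape} "
                    f"vs model {value.data.shape}")
            value.data = arr.copy()
        for cname, child in self._children():
            child.load_state_dict(state, prefix + cname + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """2-D convolution on (N, H, W, C) input; weights (kh, kw, Cin, Cout)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            he_init(rng, (kernel_size, kernel_size, in_channels, out_channels),
                    fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


def conv2d(x: Tensor, weight: Parameter, bias: Parameter,
           stride: int, padding: int) -> Tensor:
    xd = x.data
    n, h, w, c = xd.shape
    kh, kw, ci, o = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    p, s = padding, stride
    xp = np.pad(xd, ((0, 0), (p, p), (p, p), (0, 0))) if p else xd
    h2, w2 = h + 2 * p, w + 2 * p
    ho = (h2 - kh) // s + 1
    wo = (w2 - kw) // s + 1
    wd = weight.data
    xp_flat = xp.reshape(-1, c)
    out_data = np.zeros((n, ho, wo, o), dtype=np.float32)
    # one full-image GEMM per kernel offset; the shift is a strided slice
    for i in range(kh):
        for j in range(kw):
            y = (xp_flat @ wd[i, j]).reshape(n, h2, w2, o)
            out_data += y[:, i:i + s * ho:s, j:j + s * wo:s]
    out_data += bias.data

    def backward(g):
        if bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 1, 2)))
        need_x = x.requires_grad or x._backward is not None
        gxp = np.zeros_like(xp) if need_x else None
        dw = np.zeros_like(wd) if weight.requires_grad else None
        gflat = g.reshape(-1, o)
        canvas = np.zeros((n, h2, w2, o), dtype=np.float32) if dw is not None \
            else None
        for i in range(kh):
            for j in range(kw):
                if dw is not None:
                    # embed g on a padded canvas so the contraction runs
                    # over contiguous memory
                    canvas[:, i:i + s * ho:s, j:j + s * wo:s] = g
                    dw[i, j] = xp_flat.T @ canvas.reshape(-1, o)
                    canvas[:, i:i + s * ho:s, j:j + s * wo:s] = 0.0
                if need_x:
                    t = (gflat @ wd[i, j].T).reshape(n, ho, wo, c)
                    gxp[:, i:i + s * ho:s, j:j + s * wo:s] += t
        if dw is not None:
            weight.accumulate_grad(dw)
        if need_x:
            x.accumulate_grad(gxp[:, p:p + h, p:p + w] if p else gxp)

    return make_node(out_data, (x, weight, bias), backward)


class ConvTranspose2d(Module):
    """Stride-2 learned up-sampling on (N, H, W, C); kernel size equals the
    stride so output patches do not overlap and the output is exactly twice
    the input size."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator, stride: int = 2):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.weight = Parameter(
            he_init(rng, (stride, stride, in_channels, out_channels),
                    in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        n, h, w, c = xd.shape
        s = self.stride
        o = self.out_channels
        wd = self.weight.data
        out_data = np.empty((n, h * s, w * s, o), dtype=np.float32)
        xflat = xd.reshape(-1, c)
        for i in range(s):
            for j in range(s):
                out_data[:, i::s, j::s] = (xflat @ wd[i, j]).reshape(n, h, w, o)
        out_data += self.bias.data
        weight, bias = self.weight, self.bias

        def backward(g):
            if bias.requires_grad:
                bias.accumulate_grad(g.sum(axis=(0, 1, 2)))
            need_x = x.requires_grad or x._backward is not None
            gx_flat = np.zeros((n * h * w, c), dtype=np.float32) if need_x \
                else None
            dw = np.zeros_like(wd) if weight.requires_grad else None
            for i in range(s):
                for j in range(s):
                    gblock = np.ascontiguousarray(g[:, i::s, j::s]) \
                        .reshape(-1, o)
                    if dw is not None:
                        dw[i, j] = xflat.T @ gblock
                    if need_x:
                        gx_flat += gblock @ wd[i, j].T
            if dw is not None:
                weight.accumulate_grad(dw)
            if need_x:
                x.accumulate_grad(gx_flat.reshape(n, h, w, c))

        return make_node(out_data, (x, weight, bias), backward)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, channels last."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = Tensor(np.zeros(channels, dtype=np.float32))
        self.running_var = Tensor(np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        gamma, beta = self.gamma, self.beta
        if self.training:
            flat = xd.reshape(-1, self.channels)
            mean = flat.mean(axis=0)
            var = np.einsum('nc,nc->c', flat, flat) / flat.shape[0] \
                - mean * mean
            var = np.maximum(var, 0.0)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mean
            self.running_var.data = (1 - m) * self.running_var.data + m * var
        else:
            mean = self.running_mean.data
            var = self.running_var.data
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (xd - mean.astype(np.float32)) * invstd
        out_data = gamma.data * xhat + beta.data
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma.accumulate_grad((g * xhat).sum(axis=(0, 1, 2)))
            if beta.requires_grad:
                beta.accumulate_grad(g.sum(axis=(0, 1, 2)))
            if not (x.requires_grad or x._backward is not None):
                return
            dxhat = g * gamma.data
            if training:
                mu1 = dxhat.mean(axis=(0, 1, 2))
                mu2 = (dxhat * xhat).mean(axis=(0, 1, 2))
                x.accumulate_grad(invstd * (dxhat - mu1 - xhat * mu2))
            else:
                x.accumulate_grad(invstd * dxhat)

        return make_node(out_data, (x, gamma, beta), backward)


class MaxPool2d(Module):
    """Non-overlapping max pooling on (N, H, W, C)."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        n, h, w, c = xd.shape
        k = self.size
        if h % k or w % k:
            raise ValueError(f"max-pool of size {k} needs divisible input, "
                             f"got {h}x{w}")
        ho, wo = h // k, w // k
        windows = xd.reshape(n, ho, k, wo, k, c).transpose(0, 1, 3, 5, 2, 4) \
            .reshape(n, ho, wo, c, k * k)
        idx = windows.argmax(axis=-1)
        out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gw = np.zeros((n, ho, wo, c, k * k), dtype=np.float32)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n, ho, wo, c, k, k).transpose(0, 1, 4, 2, 5, 3) \
                .reshape(n, h, w, c)
            x.accumulate_grad(gx)

        return make_node(out_data, (x,), backward)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_init(rng, (in_features, out_features),
                                        in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


__all__ = [
    "Parameter", "Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "MaxPool2d", "Linear", "conv2d", "relu", "leaky_relu", "sigmoid", "he_init",
]
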
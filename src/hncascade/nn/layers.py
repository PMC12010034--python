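"""Neural-network layers for 3D volumetric segmentation.

Convolutions are implemented as im2col + matmul; the gradient with respect
to the input is scattered back with a cached flat-index ``bincount``, which
keeps a full training step vectorized. Tensors are (N, C, X, Y, Z) with
N = 1 in this pipeline (batch size 1).
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, accumulate

Array = np.ndarray


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, Array]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{name}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, Array]:
        state = {f"param.{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer.{k}": b.copy() for k, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, Array]) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[f"param.{k}"], dtype=np.float32)
        for k, _ in list(self.buffers()):
            parts = k.split(".")
            obj = self
            for part in parts[:-1]:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            setattr(obj, parts[-1], np.asarray(state[f"buffer.{k}"]))

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---- conv machinery ------------------------------------------------------

def _corr3d(xd: Array, w: Array, stride: int, pad_lo: tuple[int, int, int],
            pad_hi: tuple[int, int, int]) -> tuple[Array, Array]:
    """Raw strided cross-correlation via im2col + matmul.

    xd: (N, Cin, X, Y, Z), w: (Cout, Cin, k, k, k).
    Returns (out (N, Cout, ox, oy, oz), cols (N, P, Cin*k^3)).
    """
    n, c_in = xd.shape[:2]
    c_out, _, k = w.shape[:3]
    if any(pad_lo) or any(pad_hi):
        xp = np.pad(xd, ((0, 0), (0, 0)) + tuple(zip(pad_lo, pad_hi)))
    else:
        xp = xd
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    ox, oy, oz = win.shape[2:5]
    P = ox * oy * oz
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(n, P, c_in * k**3)
    out = cols @ w.reshape(c_out, -1).T  # (N, P, Cout)
    out = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, c_out, ox, oy, oz)
    return out, cols


def conv3d(x: Tensor, weight: Parameter, bias: Optional[Parameter],
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation. weight: (Cout, Cin, k, k, k)."""
    xd = x.data
    n, c_in, X, Y, Z = xd.shape
    c_out, _, k, _, _ = weight.data.shape
    out_data, cols = _corr3d(xd, weight.data, stride, (padding,) * 3, (padding,) * 3)
    if bias is not None:
        out_data += bias.data.reshape(1, c_out, 1, 1, 1)
    ox, oy, oz = out_data.shape[2:]
    P = ox * oy * oz
    parents = (x, weight) + ((bias,) if bias is not None else ())
    result = Tensor(out_data, parents)

    def backward(g: Array) -> None:
        gm = np.ascontiguousarray(g.reshape(n, c_out, P).transpose(0, 2, 1))  # (N, P, Cout)
        if weight.requires_grad:
            gw = sum(gm[b].T @ cols[b] for b in range(n))  # (Cout, Cin*k^3)
            accumulate(weight, gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            accumulate(bias, gm.sum(axis=(0, 1)))
        if x.requires_grad:
            # dx is the stride-dilated gradient correlated with the flipped
            # kernel (the transposed convolution), again as im2col matmuls
            if stride > 1:
                dil = np.zeros((n, c_out, stride * (ox - 1) + 1,
                                stride * (oy - 1) + 1, stride * (oz - 1) + 1),
                               dtype=np.float32)
                dil[:, :, ::stride, ::stride, ::stride] = g
            else:
                dil = g
            wflip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            pad_lo = (k - 1 - padding,) * 3
            pad_hi = tuple(
                dim + padding - stride * (o - 1) - 1
                for dim, o in zip((X, Y, Z), (ox, oy, oz))
            )
            assert all(p >= 0 for p in pad_hi), "inconsistent conv geometry"
            gx, _ = _corr3d(dil, np.ascontiguousarray(wflip), 1, pad_lo, pad_hi)
            accumulate(x, gx)

    result.backward_fn = backward
    return result


def conv_transpose3d_2x(x: Tensor, weight: Parameter, bias: Optional[Parameter]) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    weight: (Cin, Cout, 2, 2, 2); output spatial dims are twice the input's.
    """
    xd = x.data
    n, c_in, X, Y, Z = xd.shape
    c_out = weight.data.shape[1]
    out6 = np.einsum("ncxyz,cdabg->ndxaybzg", xd, weight.data, optimize=True)
    out_data = out6.reshape(n, c_out, 2 * X, 2 * Y, 2 * Z)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, c_out, 1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    result = Tensor(out_data, parents)

    def backward(g: Array) -> None:
        g6 = g.reshape(n, c_out, X, 2, Y, 2, Z, 2)
        if x.requires_grad:
            gx = np.einsum("ndxaybzg,cdabg->ncxyz", g6, weight.data, optimize=True)
            accumulate(x, gx.astype(np.float32))
        if weight.requires_grad:
            gw = np.einsum("ncxyz,ndxaybzg->cdabg", xd, g6, optimize=True)
            accumulate(weight, gw.astype(np.float32))
        if bias is not None and bias.requires_grad:
            accumulate(bias, g.sum(axis=(0, 2, 3, 4)))

    result.backward_fn = backward
    return result


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: Optional[np.random.Generator] = None,
                 bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel**3
        std = float(np.sqrt(2.0 / fan_in))  # He fan-in, suits rectifier nets
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d2x(Module):
    def __init__(self, c_in: int, c_out: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * 8
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out, 2, 2, 2)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d_2x(x, self.weight, self.bias)


class BatchNorm3d(Module):
    """Per-channel normalization over the batch and spatial axes.

    With batch size 1 (this pipeline's regime) the batch statistics are
    per-volume statistics; using stale running averages at inference makes
    evaluation erratic, so by default the same batch statistics are used in
    eval mode too (``use_running_stats=True`` restores textbook behavior).
    Running averages are still tracked and checkpointed.
    """

    use_running_stats = False

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.2):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training or not self.use_running_stats:
            mu = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            if self.training:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu).astype(np.float32)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (xd - mu.reshape(shape)) / std.reshape(shape)
        out_data = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        result = Tensor(out_data, (x, self.gamma, self.beta))
        batch_stats = self.training or not self.use_running_stats
        gamma, beta = self.gamma, self.beta

        def backward(g: Array) -> None:
            if gamma.requires_grad:
                accumulate(gamma, (g * xhat).sum(axis=axes))
            if beta.requires_grad:
                accumulate(beta, g.sum(axis=axes))
            if x.requires_grad:
                gs = g * gamma.data.reshape(shape)
                if batch_stats:
                    gx = (gs - gs.mean(axis=axes, keepdims=True)
                          - xhat * (gs * xhat).mean(axis=axes, keepdims=True)) / std.reshape(shape)
                else:
                    gx = gs / std.reshape(shape)
                accumulate(x, gx.astype(np.float32))

        result.backward_fn = backward
        return result


class PReLU(Module):
    """Parametric rectifier with one learnable slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.full(channels, init))

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        shape = (1, -1) + (1,) * (xd.ndim - 2)
        a = self.alpha.data.reshape(shape)
        neg = np.minimum(xd, 0.0)
        out_data = np.maximum(xd, 0.0) + a * neg
        result = Tensor(out_data, (x, self.alpha))
        alpha = self.alpha

        def backward(g: Array) -> None:
            if x.requires_grad:
                accumulate(x, (g * np.where(xd > 0, 1.0, a)).astype(np.float32))
            if alpha.requires_grad:
                accumulate(alpha, (g * neg).sum(axis=(0,) + tuple(range(2, xd.ndim))))

        result.backward_fn = backward
        return result
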
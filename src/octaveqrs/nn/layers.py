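"""Trainable layers for the detector, built on the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from ..octconv import OctConvLayer, split_channels
from .autodiff import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "OctConv1d",
    "OctBatchNorm",
    "Dropout",
    "BiGRU",
    "Dense",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (v for v in value if isinstance(v, Module))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    @property
    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpoint support -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All stateful arrays in a fixed traversal order (params + buffers)."""
        arrays: list[np.ndarray] = [p.data for p in self.parameters()]
        arrays.extend(self._buffers())
        return arrays

    def _buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                bufs.extend(value._buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        bufs.extend(item._buffers())
        return bufs

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state has {len(arrays)} arrays, expected {len(own)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class OctConv1d(Module):
    """One octave convolution with trainable weights.

    Operates on an (optional) pair of branch tensors; either branch may be
    ``None`` per the layer's octave ratios.  Bias is added once per output
    channel after the two contributing paths are summed.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_length: int,
        alpha_in: float,
        alpha_out: float,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        init = OctConvLayer.init_glorot(
            kernel_length, in_channels, out_channels, alpha_in, alpha_out, rng
        )
        self.alpha_in = alpha_in
        self.alpha_out = alpha_out
        self.kernel_length = kernel_length
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w_hh = Parameter(init.w_hh.astype(dtype)) if init.w_hh.size else None
        self.w_hl = Parameter(init.w_hl.astype(dtype)) if init.w_hl.size else None
        self.w_lh = Parameter(init.w_lh.astype(dtype)) if init.w_lh.size else None
        self.w_ll = Parameter(init.w_ll.astype(dtype)) if init.w_ll.size else None
        self.bias_high = Parameter(init.bias_high.astype(dtype)) if init.bias_high.size else None
        self.bias_low = Parameter(init.bias_low.astype(dtype)) if init.bias_low.size else None

    def parameters(self) -> list[Parameter]:
        return [
            p
            for p in (self.w_hh, self.w_hl, self.w_lh, self.w_ll, self.bias_high, self.bias_low)
            if p is not None
        ]

    def __call__(
        self, high: Tensor | None, low: Tensor | None
    ) -> tuple[Tensor | None, Tensor | None]:
        oh, ol = split_channels(self.out_channels, self.alpha_out)
        y_high = y_low = None
        if oh:
            parts = []
            if high is not None and self.w_hh is not None:
                parts.append(high.conv1d(self.w_hh))
            if low is not None and self.w_lh is not None:
                parts.append(low.conv1d(self.w_lh).upsample_double())
            y_high = parts[0] if len(parts) == 1 else parts[0] + parts[1]
            y_high = y_high + self.bias_high
        if ol:
            parts = []
            if low is not None and self.w_ll is not None:
                parts.append(low.conv1d(self.w_ll))
            if high is not None and self.w_hl is not None:
                parts.append(high.avg_pool_halve().conv1d(self.w_hl))
            y_low = parts[0] if len(parts) == 1 else parts[0] + parts[1]
            y_low = y_low + self.bias_low
        return y_high, y_low


class _BatchNorm1d(Module):
    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def _buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        return x.batch_norm(
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class OctBatchNorm(Module):
    """Independent per-channel batch normalization of each frequency branch."""

    def __init__(self, channels: int, alpha: float, dtype=np.float32):
        c_high, c_low = split_channels(channels, alpha)
        self.bn_high = _BatchNorm1d(c_high, dtype) if c_high else None
        self.bn_low = _BatchNorm1d(c_low, dtype) if c_low else None

    def __call__(
        self, high: Tensor | None, low: Tensor | None
    ) -> tuple[Tensor | None, Tensor | None]:
        yh = self.bn_high(high) if (self.bn_high is not None and high is not None) else None
        yl = self.bn_low(low) if (self.bn_low is not None and low is not None) else None
        return yh, yl


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Draws masks from the rng
    installed by the owning network so runs are reproducible per seed."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


def _glorot_matrix(rng: np.random.Generator, d_in: int, d_out: int, dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out)).astype(dtype)


class _GRUDirection(Module):
    """One direction of a GRU with reset/update gates.

    Gate order in the packed matrices is [reset | update | candidate]; the
    candidate recurrent term applies the reset gate to the previous hidden
    state before the recurrent weight, h_cand = tanh(W x + U (r * h)).
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.hidden = hidden
        self.w_x = Parameter(_glorot_matrix(rng, input_size, 3 * hidden, dtype))
        self.w_h = Parameter(_glorot_matrix(rng, hidden, 3 * hidden, dtype))
        self.bias = Parameter(np.zeros(3 * hidden, dtype=dtype))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        hd = self.hidden
        a = x_t @ self.w_x + self.bias
        rec = h @ self.w_h.slice_last(0, 2 * hd)
        r = (a.slice_last(0, hd) + rec.slice_last(0, hd)).sigmoid()
        z = (a.slice_last(hd, 2 * hd) + rec.slice_last(hd, 2 * hd)).sigmoid()
        cand = (a.slice_last(2 * hd, 3 * hd) + (r * h) @ self.w_h.slice_last(2 * hd, 3 * hd)).tanh()
        one = Tensor(np.ones((), dtype=h.dtype))
        return (one - z) * h + z * cand

    def run(self, xs: list[Tensor], reverse: bool) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.hidden), dtype=xs[0].data.dtype))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: dict[int, Tensor] = {}
        for t in order:
            h = self.step(xs[t], h)
            out[t] = h
        return [out[t] for t in range(len(xs))]


class BiGRU(Module):
    """Bidirectional GRU over a short frame sequence; outputs are the
    concatenated forward and backward hidden states (2 x hidden)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fwd = _GRUDirection(input_size, hidden, rng, dtype)
        self.bwd = _GRUDirection(input_size, hidden, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, D) -> (B, T, 2*hidden)."""
        b, t, d = x.data.shape
        xt = x.transpose(0, 2, 1)  # (B, D, T)
        xs = [xt.slice_last(i, i + 1).reshape(b, d) for i in range(t)]
        hf = self.fwd.run(xs, reverse=False)
        hb = self.bwd.run(xs, reverse=True)
        steps = [
            concat([f, bk], axis=-1).reshape(b, 1, 2 * self.fwd.hidden)
            for f, bk in zip(hf, hb)
        ]
        return concat(steps, axis=1)


class Dense(Module):
    """Affine map applied to the last axis (shared across timesteps)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Parameter(_glorot_matrix(rng, d_in, d_out, dtype))
        self.bias = Parameter(np.zeros(d_out, dtype=dtype))
        self.d_in = d_in
        self.d_out = d_out

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.data.shape
        flat = x.reshape(int(np.prod(shape[:-1])), shape[-1])
        y = flat @ self.weight + self.bias
        return y.reshape(*shape[:-1], self.d_out)
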
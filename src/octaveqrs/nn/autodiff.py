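"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; :meth:`Tensor.backward` runs the chain rule through the recorded graph.
Only the operations the detector needs are provided, each with a
hand-written vector-Jacobian product.  Heavy operations (convolution via
im2col, batch normalization) are single fused primitives so the hot path
stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

from ..octconv import same_padding

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "retain_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self.retain_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # Adopted arrays are never mutated in place: fan-in > 1 allocates.
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (defaults to scalar seed 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if not node.retain_grad:
                    node.grad = None  # free intermediate gradients
            # release graph edges (and the activations their closures hold)
            # as soon as a node is processed; a graph is traversed once
            node._backward = None
            node._prev = ()

    # -- elementwise arithmetic -------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars from upcasting float32 graphs to float64
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    # -- matmul ------------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - y * y))

        return self._make(y, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def slice_last(self, start: int, stop: int) -> "Tensor":
        """Static slice along the last axis."""
        sl = (Ellipsis, slice(start, stop))

        def backward(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accumulate(full)

        return self._make(self.data[sl], (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            self._accumulate(np.full_like(self.data, g / n))

        return self._make(np.asarray(self.data.mean()), (self,), backward)

    def sum_axis(self, axis: int, keepdims: bool = False) -> "Tensor":
        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    # -- fused signal primitives --------------------------------------------
    # Network activations are laid out channels-last, (batch, time, channel):
    # stride-1 convolution then reduces to one large GEMM per kernel tap
    # with no im2col gather, which keeps the hot path inside BLAS.

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Length-preserving stride-1 cross-correlation on (B, L, C) input.

        ``weight`` is [out_channels, in_channels, kernel_length].  For each
        kernel tap j the padded input matrix (B*Lp, C_in) is multiplied by
        the tap's (C_in, C_out) matrix and the result is accumulated at the
        corresponding temporal shift; the backward pass mirrors this with
        transposed GEMMs.
        """
        x = self
        b_, length, c_in = x.data.shape
        c_out, wc_in, k = weight.data.shape
        if wc_in != c_in:
            raise ValueError(f"input has {c_in} channels but weights expect {wc_in}")
        pl, pr = same_padding(k)
        lp = length + k - 1
        xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
        xf = xp.reshape(b_ * lp, c_in)
        taps = np.ascontiguousarray(weight.data.transpose(2, 1, 0))  # (k, C_in, C_out)
        y = np.zeros((b_, length, c_out), dtype=x.data.dtype)
        for j in range(k):
            z = (xf @ taps[j]).reshape(b_, lp, c_out)
            y += z[:, j : j + length]
        if bias is not None:
            y += bias.data
        keep_pad = any(p.requires_grad for p in (x, weight))
        if not keep_pad:
            xp = None

        def backward(g):
            gf = np.ascontiguousarray(g).reshape(b_ * length, c_out)
            if weight.requires_grad:
                dw = np.empty((k, c_in, c_out), dtype=g.dtype)
                for j in range(k):
                    sl = np.ascontiguousarray(xp[:, j : j + length]).reshape(-1, c_in)
                    dw[j] = sl.T @ gf
                weight._accumulate(dw.transpose(2, 1, 0))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1)))
            if x.requires_grad:
                dxp = np.zeros((b_, lp, c_in), dtype=g.dtype)
                for j in range(k):
                    dxp[:, j : j + length] += (gf @ taps[j].T).reshape(b_, length, c_in)
                x._accumulate(dxp[:, pl : pl + length])

        parents = (x, weight) if bias is None else (x, weight, bias)
        return self._make(y, parents, backward)

    def avg_pool_halve(self) -> "Tensor":
        b_, length, c = self.data.shape
        y = self.data.reshape(b_, length // 2, 2, c).mean(axis=2)

        def backward(g):
            self._accumulate(np.repeat(g, 2, axis=1) * np.asarray(0.5, dtype=g.dtype))

        return self._make(y, (self,), backward)

    def upsample_double(self) -> "Tensor":
        b_, length, c = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(b_, length, 2, c).sum(axis=2))

        return self._make(np.repeat(self.data, 2, axis=1), (self,), backward)

    def segment_mean(self, n_segments: int) -> "Tensor":
        """(B, L, C) -> (B, n_segments, C): time-mean over equal segments."""
        b_, length, c = self.data.shape
        if length % n_segments:
            raise ValueError(f"length {length} not divisible into {n_segments} segments")
        m = length // n_segments
        y = self.data.reshape(b_, n_segments, m, c).mean(axis=2)

        def backward(g):
            gg = g[:, :, None, :] / np.asarray(m, dtype=g.dtype)
            self._accumulate(np.broadcast_to(gg, (b_, n_segments, m, c)).reshape(self.data.shape))

        return self._make(y, (self,), backward)

    def batch_norm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel batch normalization over (B, L, C).

        In training mode statistics are computed over batch and time and the
        running estimates are updated in place; in eval mode the running
        estimates are used and no graph is recorded through them.
        """
        x = self
        n = x.data.shape[0] * x.data.shape[1]
        if training:
            mu = x.data.mean(axis=(0, 1))
            xc = x.data - mu
            var = np.einsum("blc,blc->c", xc, xc) / n
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var * (n / max(n - 1, 1))
        else:
            mu, var = running_mean, running_var
            xc = x.data - mu
        inv_std = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
        scale = gamma.data * inv_std
        y = xc * scale + beta.data

        def backward(g):
            # sums fused with einsum; xhat = xc * inv_std is never materialized
            g_sum = np.einsum("blc->c", g)
            g_xc_sum = np.einsum("blc,blc->c", g, xc)
            if gamma.requires_grad:
                gamma._accumulate(g_xc_sum * inv_std)
            if beta.requires_grad:
                beta._accumulate(g_sum)
            if x.requires_grad:
                if training:
                    dx = g * scale
                    dx -= (scale * g_sum) / n
                    dx -= xc * ((gamma.data * inv_std**3 * g_xc_sum) / n)
                else:
                    dx = g * scale
                x._accumulate(dx)

        return self._make(y, (x, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out
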
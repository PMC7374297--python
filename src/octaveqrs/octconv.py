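"""1-D octave convolution and its resampling primitives.

Feature maps are real arrays laid out ``[channel, time]`` with an optional
leading batch axis.  An octave-factorized map keeps a high-frequency group of
channels at full temporal resolution and a low-frequency group at half
resolution; the fraction of channels assigned to the low group is the octave
ratio ``alpha``.  One octave convolution mixes the two groups through four
weight paths (high->high, high->low, low->high, low->low), pooling or
upsampling by a factor of two where the resolutions differ.

All convolutions here are stride-1, length-preserving cross-correlations
(deep-learning convention: no kernel flip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyFactorizedMap",
    "OctConvLayer",
    "split_channels",
    "same_padding",
    "average_pool_halve",
    "upsample_double",
    "conv1d",
    "octconv_forward",
]


def split_channels(channels: int, alpha: float) -> tuple[int, int]:
    """Partition ``channels`` into (high, low) groups for octave ratio ``alpha``.

    The low-frequency group gets ``round(alpha * channels)`` channels.  For
    the configurations used by the detector (alpha a multiple of 0.25,
    channel counts 64/128) the split is exact.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    c_low = int(math.floor(alpha * channels + 0.5))
    return channels - c_low, c_low


def same_padding(kernel_length: int) -> tuple[int, int]:
    """Left/right zero padding that preserves length at stride 1.

    Odd kernels pad symmetrically; even kernels pad one less on the left
    (k/2 - 1, k/2), matching common framework behaviour.
    """
    if kernel_length < 1:
        raise ValueError("kernel_length must be >= 1")
    if kernel_length % 2 == 0:
        return kernel_length // 2 - 1, kernel_length // 2
    return kernel_length // 2, kernel_length // 2


def _as_batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.ndim == 2:
        return x[None], False
    if x.ndim == 3:
        return x, True
    raise ValueError(f"expected [channel, time] or [batch, channel, time], got shape {x.shape}")


def average_pool_halve(x: np.ndarray) -> np.ndarray:
    """Average-pool with kernel 2 and stride 2, halving the time axis."""
    xb, batched = _as_batched(x)
    b, c, length = xb.shape
    if length % 2 != 0:
        raise ValueError(
            f"octave factorization requires even window lengths; got length {length}"
        )
    out = xb.reshape(b, c, length // 2, 2).mean(axis=-1)
    return out if batched else out[0]


def upsample_double(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour upsampling by 2: out[t] = in[t // 2]."""
    xb, batched = _as_batched(x)
    out = np.repeat(xb, 2, axis=-1)
    return out if batched else out[0]


def im2col(x: np.ndarray, kernel_length: int) -> np.ndarray:
    """Unfold a batched map (B, C, L) into sliding windows (B*L, C*k).

    Zero-pads per :func:`same_padding` so there is one window per time step.
    Shared by the forward convolution and the training engine's backward pass.
    """
    b, c, length = x.shape
    pl, pr = same_padding(kernel_length)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel_length, axis=2)
    # (B, C, L, k) -> (B, L, C, k) -> (B*L, C*k)
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * length, c * kernel_length)


def conv1d(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
    ) -> np.ndarray:
    """Length-preserving 1-D cross-correlation.

    Parameters
    ----------
    x : array, [channel, time] or [batch, channel, time]
    weights : array, [out_channels, in_channels, kernel_length]
    bias : array, [out_channels], optional

    Returns
    -------
    array with the same layout as ``x`` and ``out_channels`` channels.
    """
    xb, batched = _as_batched(x)
    b, c, length = xb.shape
    if weights.ndim != 3:
        raise ValueError("weights must be [out_channels, in_channels, kernel_length]")
    c_out, c_in, k = weights.shape
    if c_in != c:
        raise ValueError(f"input has {c} channels but weights expect {c_in}")
    cols = im2col(xb, k)
    y = cols @ weights.reshape(c_out, c_in * k).T  # (B*L, c_out)
    y = y.reshape(b, length, c_out).transpose(0, 2, 1)
    if bias is not None:
        y = y + np.asarray(bias).reshape(1, c_out, 1)
    return y if batched else y[0]


@dataclass
class FrequencyFactorizedMap:
    """A feature map factorized into high- and low-frequency channel groups.

    ``high`` has shape (..., c_high, L) and ``low`` shape (..., c_low, L/2);
    either may be ``None`` when alpha is 0 (no low branch) or 1 (no high
    branch).
    """

    high: np.ndarray | None
    low: np.ndarray | None
    alpha: float

    def __post_init__(self) -> None:
        if self.high is None and self.low is None:
            raise ValueError("at least one frequency branch must be present")
        if self.high is not None and self.low is not None:
            if self.low.shape[-1] * 2 != self.high.shape[-1]:
                raise ValueError(
                    "low branch must have half the temporal length of the high branch"
                )

    @classmethod
    def from_full(cls, x: np.ndarray, alpha: float) -> "FrequencyFactorizedMap":
        """Factorize a full-resolution map: first (1-alpha)c channels stay
        high-frequency, the rest are average-pooled into the low branch."""
        xb, batched = _as_batched(x)
        c_high, c_low = split_channels(xb.shape[1], alpha)
        high = xb[:, :c_high] if c_high else None
        low = average_pool_halve(xb[:, c_high:]) if c_low else None
        if not batched:
            high = None if high is None else high[0]
            low = None if low is None else low[0]
        return cls(high=high, low=low, alpha=alpha)

    def to_full(self) -> np.ndarray:
        """Concatenate branches back to full resolution (low is upsampled)."""
        parts = []
        if self.high is not None:
            parts.append(self.high)
        if self.low is not None:
            parts.append(upsample_double(self.low))
        return np.concatenate(parts, axis=-2)


def _glorot(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> np.ndarray:
    limit = math.sqrt(6.0 / ((c_in + c_out) * k)) if c_in + c_out else 0.0
    return rng.uniform(-limit, limit, size=(c_out, c_in, k))


@dataclass
class OctConvLayer:
    """Weights of one 1-D octave convolution.

    The four groups partition a vanilla kernel of shape
    ``[out_channels, in_channels, kernel_length]`` along both channel axes,
    so the total parameter count is independent of the octave ratios.
    """

    kernel_length: int
    in_channels: int
    out_channels: int
    alpha_in: float
    alpha_out: float
    w_hh: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    w_hl: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    w_lh: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    w_ll: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    bias_high: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    bias_low: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ih, il = split_channels(self.in_channels, self.alpha_in)
        oh, ol = split_channels(self.out_channels, self.alpha_out)
        k = self.kernel_length
        shapes = {
            "w_hh": (oh, ih, k),
            "w_hl": (ol, ih, k),
            "w_lh": (oh, il, k),
            "w_ll": (ol, il, k),
            "bias_high": (oh,),
            "bias_low": (ol,),
        }
        for name, shape in shapes.items():
            cur = getattr(self, name)
            if cur is None:
                setattr(self, name, np.zeros(shape))
            elif tuple(cur.shape) != shape:
                raise ValueError(f"{name} must have shape {shape}, got {cur.shape}")

    @classmethod
    def init_glorot(
        cls,
        kernel_length: int,
        in_channels: int,
        out_channels: int,
        alpha_in: float,
        alpha_out: float,
        rng: np.random.Generator,
    ) -> "OctConvLayer":
        """Xavier/Glorot-uniform initialization of all four weight groups.

        The fan is computed from the FULL (unsplit) channel counts so the
        draw statistics match a vanilla convolution of the same size.
        """
        ih, il = split_channels(in_channels, alpha_in)
        oh, ol = split_channels(out_channels, alpha_out)
        limit = math.sqrt(6.0 / ((in_channels + out_channels) * kernel_length))
        u = lambda co, ci: rng.uniform(-limit, limit, size=(co, ci, kernel_length))
        return cls(
            kernel_length,
            in_channels,
            out_channels,
            alpha_in,
            alpha_out,
            w_hh=u(oh, ih),
            w_hl=u(ol, ih),
            w_lh=u(oh, il),
            w_ll=u(ol, il),
            bias_high=np.zeros(oh),
            bias_low=np.zeros(ol),
        )

    @classmethod
    def from_vanilla(
        cls,
        weights: np.ndarray,
        bias: np.ndarray,
        alpha_in: float,
        alpha_out: float,
    ) -> "OctConvLayer":
        """Split a vanilla kernel [c_out, c_in, k] into the four octave groups."""
        c_out, c_in, k = weights.shape
        ih, _ = split_channels(c_in, alpha_in)
        oh, _ = split_channels(c_out, alpha_out)
        return cls(
            k,
            c_in,
            c_out,
            alpha_in,
            alpha_out,
            w_hh=weights[:oh, :ih],
            w_hl=weights[oh:, :ih],
            w_lh=weights[:oh, ih:],
            w_ll=weights[oh:, ih:],
            bias_high=np.asarray(bias)[:oh],
            bias_low=np.asarray(bias)[oh:],
        )

    @property
    def num_parameters(self) -> int:
        return sum(
            w.size
            for w in (self.w_hh, self.w_hl, self.w_lh, self.w_ll, self.bias_high, self.bias_low)
        )


def octconv_forward(x: FrequencyFactorizedMap, layer: OctConvLayer) -> FrequencyFactorizedMap:
    """Apply one octave convolution.

    The high-frequency output sums the intra-frequency path with the
    upsampled low->high path; the low-frequency output sums the intra-path
    with the pooled high->low path.  Absent branches contribute nothing.
    Bias is added once per output channel after the two paths are summed.
    """
    if not math.isclose(x.alpha, layer.alpha_in, abs_tol=1e-9):
        raise ValueError(
            f"input map alpha {x.alpha} does not match layer alpha_in {layer.alpha_in}"
        )
    oh, ol = split_channels(layer.out_channels, layer.alpha_out)
    if ol and x.high is not None and x.high.shape[-1] % 2 != 0:
        raise ValueError("high branch length must be even when alpha_out > 0")

    y_high = None
    y_low = None
    if oh:
        terms = []
        if x.high is not None and layer.w_hh.size:
            terms.append(conv1d(x.high, layer.w_hh))
        if x.low is not None and layer.w_lh.size:
            terms.append(upsample_double(conv1d(x.low, layer.w_lh)))
        y_high = sum(terms) if terms else None
        if y_high is None:
            raise ValueError("no input branch feeds the high-frequency output")
        y_high = y_high + layer.bias_high.reshape(-1, 1)
    if ol:
        terms = []
        if x.low is not None and layer.w_ll.size:
            terms.append(conv1d(x.low, layer.w_ll))
        if x.high is not None and layer.w_hl.size:
            terms.append(conv1d(average_pool_halve(x.high), layer.w_hl))
        y_low = sum(terms) if terms else None
        if y_low is None:
            raise ValueError("no input branch feeds the low-frequency output")
        y_low = y_low + layer.bias_low.reshape(-1, 1)
    return FrequencyFactorizedMap(high=y_high, low=y_low, alpha=layer.alpha_out)
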
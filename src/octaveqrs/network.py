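"""The fetal-QRS detector architecture.

A 4 x 1000 one-second abdominal window passes through a convolutional trunk
of three residual blocks built from 1-D octave convolutions (kernel lengths
8/5/3 inside each block, 64/128/128 filters per block, each convolution
followed by batch normalization and ReLU, a 1x1 convolution shortcut
bridging every block).  The 128 x 1000 trunk output is split into ten
100-sample frames, each global-average pooled to a 128-vector; a
bidirectional GRU (hidden 32) integrates the ten-frame sequence and a shared
affine softmax head emits one fQRS-present probability pair per frame.

The octave ratio ``alpha`` assigns a fraction of channels to a half-rate
low-frequency branch throughout the trunk; the first convolution enters the
factorized representation (alpha_in = 0) and the last one leaves it
(alpha_out = 0), so the trunk consumes and produces ordinary full-rate maps.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .costmodel import LayerCostSpec
from .nn import BiGRU, Dense, Dropout, Module, OctBatchNorm, OctConv1d, Tensor
from .nn.autodiff import no_grad as nn_no_grad

__all__ = [
    "NetworkConfig",
    "FramePredictions",
    "OctResNet",
    "build_network",
    "conv_layer_plan",
    "segment_pool",
    "gru_cell",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of the detector."""

    in_channels: int = 4
    window_length: int = 1000
    frames_per_window: int = 10
    block_filters: tuple[int, ...] = (64, 128, 128)
    block_kernel_lengths: tuple[int, ...] = (8, 5, 3)
    alpha: float = 0.0
    gru_hidden: int = 32
    dropout_rate: float = 0.4
    num_classes: int = 2
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.window_length % self.frames_per_window != 0:
            raise ValueError("window_length must be divisible by frames_per_window")
        if self.window_length % 2 != 0:
            raise ValueError("octave factorization requires an even window_length")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if len(self.block_filters) != len(self.block_kernel_lengths):
            raise ValueError("block_filters and block_kernel_lengths must have equal length")

    @property
    def frame_length(self) -> int:
        return self.window_length // self.frames_per_window

    def with_alpha(self, alpha: float) -> "NetworkConfig":
        return replace(self, alpha=alpha)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_filters"] = list(self.block_filters)
        d["block_kernel_lengths"] = list(self.block_kernel_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("block_filters", "block_kernel_lengths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FramePredictions:
    """Per-frame class probabilities for one window (rows sum to one)."""

    probabilities: np.ndarray  # (frames, 2)
    labels: np.ndarray | None = None

    @property
    def positive(self) -> np.ndarray:
        return self.probabilities[:, 1]

    @property
    def predicted(self) -> np.ndarray:
        return np.argmax(self.probabilities, axis=-1)


def conv_layer_plan(config: NetworkConfig) -> list[LayerCostSpec]:
    """Dimensions and octave ratios of every convolution in the trunk.

    Nine block convolutions plus one 1x1 shortcut per block, in forward
    order.  The first convolution has alpha_in = 0, the last alpha_out = 0;
    shortcuts carry their block's boundary ratios.
    """
    a = config.alpha
    specs: list[LayerCostSpec] = []
    c_prev = config.in_channels
    n_blocks = len(config.block_filters)
    for b, c_out in enumerate(config.block_filters):
        block_in_alpha = 0.0 if b == 0 else a
        c_in = c_prev
        for j, k in enumerate(config.block_kernel_lengths):
            ai = block_in_alpha if j == 0 else a
            last_conv = b == n_blocks - 1 and j == len(config.block_kernel_lengths) - 1
            ao = 0.0 if last_conv else a
            specs.append(
                LayerCostSpec(
                    length=config.window_length,
                    kernel_length=k,
                    in_channels=c_in,
                    out_channels=c_out,
                    alpha_in=ai,
                    alpha_out=ao,
                    name=f"block{b + 1}_conv{j + 1}",
                )
            )
            c_in = c_out
        block_out_alpha = 0.0 if b == n_blocks - 1 else a
        specs.append(
            LayerCostSpec(
                length=config.window_length,
                kernel_length=1,
                in_channels=c_prev,
                out_channels=c_out,
                alpha_in=block_in_alpha,
                alpha_out=block_out_alpha,
                name=f"block{b + 1}_shortcut",
            )
        )
        c_prev = c_out
    return specs


class _ResidualBlock(Module):
    """conv(k1)-BN-ReLU, conv(k2)-BN-ReLU, conv(k3)-BN, plus a 1x1
    conv-BN shortcut from the block input, then a final ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernels: tuple[int, ...],
        alpha_in: float,
        alpha_mid: float,
        alpha_out: float,
        rng: np.random.Generator,
        config: NetworkConfig,
        dtype,
    ):
        alphas_in = [alpha_in] + [alpha_mid] * (len(kernels) - 1)
        alphas_out = [alpha_mid] * (len(kernels) - 1) + [alpha_out]
        chans_in = [in_channels] + [out_channels] * (len(kernels) - 1)
        self.convs = [
            OctConv1d(ci, out_channels, k, ai, ao, rng, dtype)
            for ci, k, ai, ao in zip(chans_in, kernels, alphas_in, alphas_out)
        ]
        self.bns = [OctBatchNorm(out_channels, ao, dtype) for ao in alphas_out]
        self.shortcut = OctConv1d(in_channels, out_channels, 1, alpha_in, alpha_out, rng, dtype)
        self.shortcut_bn = OctBatchNorm(out_channels, alpha_out, dtype)
        for bn in self.bns + [self.shortcut_bn]:
            for sub in (bn.bn_high, bn.bn_low):
                if sub is not None:
                    sub.momentum = config.bn_momentum
                    sub.eps = config.bn_eps

    @staticmethod
    def _relu_pair(high, low):
        return (
            high.relu() if high is not None else None,
            low.relu() if low is not None else None,
        )

    @staticmethod
    def _add_pair(a, b):
        def add(u, v):
            if u is None:
                return v
            if v is None:
                return u
            return u + v

        return add(a[0], b[0]), add(a[1], b[1])

    def __call__(self, high, low):
        h, l = high, low
        n = len(self.convs)
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            h, l = conv(h, l)
            h, l = bn(h, l)
            if i < n - 1:
                h, l = self._relu_pair(h, l)
        sc = self.shortcut_bn(*self.shortcut(high, low))
        h, l = self._add_pair((h, l), sc)
        return self._relu_pair(h, l)


class OctResNet(Module):
    """The full detector; see the module docstring for the architecture."""

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        a = config.alpha
        n_blocks = len(config.block_filters)
        self.blocks = []
        c_prev = config.in_channels
        for b, c_out in enumerate(config.block_filters):
            self.blocks.append(
                _ResidualBlock(
                    c_prev,
                    c_out,
                    tuple(config.block_kernel_lengths),
                    alpha_in=0.0 if b == 0 else a,
                    alpha_mid=a,
                    alpha_out=0.0 if b == n_blocks - 1 else a,
                    rng=rng,
                    config=config,
                    dtype=dtype,
                )
            )
            c_prev = c_out
        self.dropout_pool = Dropout(config.dropout_rate)
        self.gru = BiGRU(config.block_filters[-1], config.gru_hidden, rng, dtype)
        self.dropout_gru = Dropout(config.dropout_rate)
        self.classifier = Dense(2 * config.gru_hidden, config.num_classes, rng, dtype)
        self.dtype = dtype
        self.last_feature: Tensor | None = None
        self.seed_dropout(0)

    def seed_dropout(self, seed: int) -> None:
        """Reset the dropout mask streams (training reproducibility)."""
        self.dropout_pool.rng = np.random.default_rng((seed, 1))
        self.dropout_gru.rng = np.random.default_rng((seed, 2))

    def forward_logits(self, x: Tensor, retain_feature: bool = False) -> Tensor:
        """(B, 4, L) window batch -> (B, frames, num_classes) logits."""
        if x.data.ndim != 3 or x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (batch, {self.config.in_channels}, {self.config.window_length}) input,"
                f" got {x.data.shape}"
            )
        if x.data.shape[2] != self.config.window_length:
            raise ValueError(f"window length must be {self.config.window_length}")
        # internal layer layout is channels-last: (batch, time, channel)
        h, l = x.transpose(0, 2, 1), None
        for block in self.blocks:
            h, l = block(h, l)
        assert l is None, "trunk must exit the octave representation"
        feature = h  # (B, L, 128): the map Grad-CAM explains
        if retain_feature:
            feature.retain_grad = True
            self.last_feature = feature
        else:
            self.last_feature = None  # avoid pinning the previous graph
        pooled = feature.segment_mean(self.config.frames_per_window)  # (B, T, C)
        pooled = self.dropout_pool(pooled)
        seq = self.dropout_gru(self.gru(pooled))
        return self.classifier(seq)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """Inference on an array of windows -> (B, frames, 2) probabilities."""
        single = windows.ndim == 2
        if single:
            windows = windows[None]
        was_training = self.training
        self.eval()
        try:
            with nn_no_grad():
                logits = self.forward_logits(Tensor(windows.astype(self.dtype))).data
        finally:
            self.train(was_training)
        probs = softmax_last(logits)
        return probs[0] if single else probs

    def predict_window(self, window: np.ndarray) -> FramePredictions:
        return FramePredictions(probabilities=self.predict_proba(window))


def softmax_last(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> OctResNet:
    """Instantiate the detector with Xavier/Glorot-initialized weights."""
    return OctResNet(config, seed=seed, dtype=dtype)


def segment_pool(features: np.ndarray, n_segments: int = 10) -> np.ndarray:
    """Global-average pool a (channels, length) map over equal time
    segments, returning (n_segments, channels)."""
    c, length = features.shape
    if length % n_segments:
        raise ValueError(f"length {length} is not divisible into {n_segments} segments")
    m = length // n_segments
    return features.reshape(c, n_segments, m).mean(axis=-1).T


def gru_cell(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    w_x: np.ndarray,
    w_h: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """One GRU update (functional, numpy).

    ``w_x``: (input, 3*hidden), ``w_h``: (hidden, 3*hidden); gate order
    [reset | update | candidate].  Implements r = sigmoid(W_r x + U_r h),
    z = sigmoid(W_z x + U_z h), h_cand = tanh(W x + U (r * h)),
    h = (1 - z) * h + z * h_cand.
    """
    hd = h_prev.shape[-1]
    if w_x.shape[-1] != 3 * hd or w_h.shape != (hd, 3 * hd):
        raise ValueError("GRU weight shapes inconsistent with hidden size")
    if x_t.shape[-1] != w_x.shape[0]:
        raise ValueError("input dimension does not match W_x")
    a = x_t @ w_x
    if bias is not None:
        a = a + bias
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    r = sig(a[..., :hd] + h_prev @ w_h[:, :hd])
    z = sig(a[..., hd : 2 * hd] + h_prev @ w_h[:, hd : 2 * hd])
    cand = np.tanh(a[..., 2 * hd :] + (r * h_prev) @ w_h[:, 2 * hd :])
    return (1.0 - z) * h_prev + z * cand


def save_checkpoint(path, network: OctResNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: config JSON + all parameter/buffer arrays."""
    arrays = network.state_arrays()
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": network.config.to_dict(),
        "dtype": np.dtype(network.dtype).name,
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        np.savez(
            fh,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"arr_{i}": a for i, a in enumerate(arrays)},
        )


def load_checkpoint(path) -> tuple[OctResNet, dict]:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    meta = json.loads(bytes(data["_meta"]).decode())
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    config = NetworkConfig.from_dict(meta["config"])
    net = OctResNet(config, seed=0, dtype=np.dtype(meta["dtype"]).type)
    arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    net.load_state_arrays(arrays)
    return net, meta["extra"]
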
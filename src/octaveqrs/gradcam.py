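"""1-D gradient-weighted class activation mapping for fQRS decisions.

For a chosen frame and class, each channel of the final 128 x 1000
convolutional feature map is weighted by the time-averaged gradient of the
frame's pre-softmax class score with respect to that channel; the ReLU of
the weighted channel sum is the attention trace.  The final feature map is
already at full temporal resolution, so the trace aligns sample-for-sample
with the input window.  One forward and one backward pass per map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_windows import standardize_windows
from .network import OctResNet
from .nn import Tensor

__all__ = ["AttentionMap", "channel_weights", "grad_cam", "grad_cam_window"]


@dataclass
class AttentionMap:
    """Non-negative per-sample attention aligned to the input window."""

    values: np.ndarray  # (window_length,)
    target_frame: int
    target_class: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("attention values must be non-negative")


def channel_weights(score_gradient: np.ndarray, frame_span: tuple[int, int]) -> np.ndarray:
    """Per-channel importance: mean gradient over the span's time positions.

    ``score_gradient`` is the (channels, length) gradient of the target
    score with respect to the final conv feature map.
    """
    start, stop = frame_span
    if not 0 <= start < stop <= score_gradient.shape[-1]:
        raise ValueError(f"invalid frame span {frame_span}")
    return score_gradient[..., start:stop].mean(axis=-1)


def _forward_with_feature(
    model: OctResNet, window: np.ndarray, normalize: bool
) -> tuple[Tensor, Tensor]:
    if window.ndim != 2:
        raise ValueError("window must be (channels, length)")
    x = window[None].astype(model.dtype)
    if normalize:
        x = standardize_windows(x).astype(model.dtype)
    was_training = model.training
    model.eval()
    try:
        logits = model.forward_logits(Tensor(x), retain_feature=True)
    finally:
        model.train(was_training)
    return logits, model.last_feature


def grad_cam(
    window: np.ndarray,
    model: OctResNet,
    target_frame: int,
    target_class: int = 1,
    span: str = "frame",
    normalize: bool = True,
) -> AttentionMap:
    """Attention trace for one (frame, class) decision on one window.

    ``span`` selects the averaging window for the channel weights: the 100
    samples of the target frame (default; the region whose pooled feature
    feeds that frame's score) or the whole window.
    """
    t = model.config.frames_per_window
    if not 0 <= target_frame < t:
        raise ValueError(f"target_frame must lie in [0, {t})")
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    logits, feature = _forward_with_feature(model, window, normalize)
    seed = np.zeros_like(logits.data)
    seed[0, target_frame, target_class] = 1.0
    logits.backward(seed)
    grad = feature.grad[0].T  # (channels, length)
    acts = feature.data[0].T
    frame_len = model.config.frame_length
    if span == "frame":
        span_idx = (target_frame * frame_len, (target_frame + 1) * frame_len)
    elif span == "window":
        span_idx = (0, model.config.window_length)
    else:
        raise ValueError("span must be 'frame' or 'window'")
    weights = channel_weights(grad, span_idx)
    values = np.maximum(weights @ acts, 0.0)
    return AttentionMap(values=values, target_frame=target_frame, target_class=target_class)


def grad_cam_window(
    window: np.ndarray,
    model: OctResNet,
    target_class: int = 1,
    normalize: bool = True,
) -> np.ndarray:
    """Whole-window attention: sum of the per-frame maps for one class."""
    total = np.zeros(model.config.window_length)
    for frame in range(model.config.frames_per_window):
        total += grad_cam(window, model, frame, target_class, normalize=normalize).values
    return total
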
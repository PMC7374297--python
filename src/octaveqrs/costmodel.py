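"""Analytic compute and memory accounting for the detector.

Counts one FLOP per multiply-accumulate, the convention under which a
stride-1 convolution over length ``l`` with kernel ``k`` costs
``l * k * c_in * c_out``.  Bias additions, batch normalization, ReLU,
pooling and up/down-sampling are excluded.  Feature-map memory is counted
in stored values: a full-resolution map costs ``l * c``, an octave map
``l*(1-alpha)*c + (l/2)*alpha*c``.

The closed forms for a single layer at equal input/output octave ratios:

* compute ratio vs. vanilla: ``1 - alpha * (1 - alpha/2)``
* memory ratio vs. full resolution: ``1 - alpha/2``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .network import NetworkConfig

__all__ = [
    "LayerCostSpec",
    "CostReport",
    "conv_flops",
    "octconv_flops",
    "flops_ratio",
    "memory_ratio",
    "layer_memory_units",
    "network_cost",
    "percent",
]


def percent(ratio: float) -> int:
    """Ratio as an integer percentage, rounding halves up (62.5% -> 63%)."""
    import math

    return int(math.floor(100.0 * ratio + 0.5))


@dataclass(frozen=True)
class LayerCostSpec:
    """Dimensions of one convolutional layer for cost accounting.

    ``length`` is the high-branch temporal length seen by the layer.
    """

    length: int
    kernel_length: int
    in_channels: int
    out_channels: int
    alpha_in: float = 0.0
    alpha_out: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.length, self.kernel_length, self.in_channels, self.out_channels) < 1:
            raise ValueError("all layer dimensions must be positive")
        for a in (self.alpha_in, self.alpha_out):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha must lie in [0, 1], got {a}")


@dataclass
class CostReport:
    """Aggregated multiply-accumulate and feature-storage costs."""

    per_layer_flops: list[float]
    layer_names: list[str]
    total_flops: float
    gru_fc_flops: float
    total_params: int
    memory_units: float
    ratio_vs_baseline: float

    def as_dict(self) -> dict:
        return {
            "layers": [
                {"name": n, "flops": f}
                for n, f in zip(self.layer_names, self.per_layer_flops)
            ],
            "cnn_flops": self.total_flops,
            "cnn_gflops": self.total_flops / 1e9,
            "gru_fc_flops": self.gru_fc_flops,
            "gru_fc_gflops": self.gru_fc_flops / 1e9,
            "total_params": self.total_params,
            "params_millions": self.total_params / 1e6,
            "memory_units": self.memory_units,
            "ratio_vs_baseline": self.ratio_vs_baseline,
        }


def conv_flops(spec: LayerCostSpec) -> float:
    """Multiply-accumulates of a vanilla (alpha = 0) convolution."""
    if spec.alpha_in != 0.0 or spec.alpha_out != 0.0:
        raise ValueError("conv_flops handles alpha = 0 only; use octconv_flops")
    return float(spec.length * spec.kernel_length * spec.in_channels * spec.out_channels)


def octconv_flops(spec: LayerCostSpec) -> float:
    """Multiply-accumulates of an octave convolution, summed over the four
    paths.  The high->high path runs at full length; the other three run at
    half length.  Reduces to :func:`conv_flops` when both ratios are zero."""
    l, k = spec.length, spec.kernel_length
    base = float(k * spec.in_channels * spec.out_channels)
    ai, ao = spec.alpha_in, spec.alpha_out
    hh = l * (1 - ai) * (1 - ao) * base
    hl = (l / 2) * (1 - ai) * ao * base
    lh = (l / 2) * ai * (1 - ao) * base
    ll = (l / 2) * ai * ao * base
    return hh + hl + lh + ll


def flops_ratio(alpha: float) -> float:
    """Per-layer compute of octave vs. vanilla convolution at equal ratios:
    ``1 - alpha * (1 - alpha/2)``, strictly decreasing on [0, 1)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return 1.0 - alpha * (1.0 - alpha / 2.0)


def memory_ratio(alpha: float) -> float:
    """Feature-storage cost of the octave representation vs. full
    resolution: ``1 - alpha/2``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return 1.0 - alpha / 2.0


def layer_memory_units(spec: LayerCostSpec) -> float:
    """Stored values of the layer's output feature map."""
    c = spec.out_channels
    return spec.length * (1 - spec.alpha_out) * c + (spec.length / 2) * spec.alpha_out * c


def _gru_fc_flops(config: "NetworkConfig") -> float:
    """Bidirectional GRU plus shared classifier multiply-accumulates.

    Per direction and timestep each of the 3 gates costs
    ``input*hidden + hidden*hidden`` MACs; the shared affine classifier maps
    the concatenated 2*hidden state to the class scores at every timestep.
    """
    h = config.gru_hidden
    d_in = config.block_filters[-1]
    t = config.frames_per_window
    gru = 2 * t * 3 * (d_in * h + h * h)
    fc = t * (2 * h) * config.num_classes
    return float(gru + fc)


def network_cost(config: "NetworkConfig") -> CostReport:
    """Whole-detector cost for one window at the configured octave ratio.

    The trunk sums :func:`octconv_flops` over the nine convolutions and the
    three 1x1 shortcut convolutions (all blocks, including the last where
    channel counts match).  The parameter count comes from instantiating the
    network and is identical for every alpha.
    """
    from .network import build_network, conv_layer_plan

    plan = conv_layer_plan(config)
    per_layer = [octconv_flops(s) for s in plan]
    total = float(sum(per_layer))
    baseline_plan = conv_layer_plan(config.with_alpha(0.0))
    baseline = float(sum(octconv_flops(s) for s in baseline_plan))
    params = build_network(config, seed=0).num_parameters
    return CostReport(
        per_layer_flops=per_layer,
        layer_names=[s.name for s in plan],
        total_flops=total,
        gru_fc_flops=_gru_fc_flops(config),
        total_params=params,
        memory_units=float(sum(layer_memory_units(s) for s in plan)),
        ratio_vs_baseline=total / baseline,
    )
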
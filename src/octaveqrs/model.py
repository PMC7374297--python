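"""High-level modelling interface: build a detector from windowed data,
fit it, and inspect the fit through a results object.

Mirrors the fit/results split of statistical modelling libraries: the
model object holds the data and configuration, ``fit()`` runs the
optimization and returns a :class:`FetalQRSResults` carrying the selected
weights, the per-epoch history, evaluation, prediction and explanation
methods, and a printable ``summary()``.
"""

from __future__ import annotations

import numpy as np

from .costmodel import network_cost
from .data_windows import Recording, extract_windows
from .gradcam import AttentionMap, grad_cam
from .network import (
    FramePredictions,
    NetworkConfig,
    OctResNet,
    build_network,
    load_checkpoint,
    save_checkpoint,
)
from .training import MetricsReport, TrainConfig, TrainResult, evaluate, train

__all__ = ["FetalQRSDetector", "FetalQRSResults"]


class FetalQRSDetector:
    """Fetal-QRS detection model over one-second abdominal windows.

    Parameters
    ----------
    train_data, val_data : list of SignalWindow or (x, y) array pairs
        Labeled 4 x 1000 windows; ``y`` holds the ten binary frame labels.
    config : NetworkConfig, optional
        Architecture hyper-parameters (octave ratio, filters, ...).
    train_config : TrainConfig, optional
        Optimization recipe.
    """

    def __init__(
        self,
        train_data,
        val_data,
        config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.train_data = train_data
        self.val_data = val_data
        self.config = config or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_recordings(
        cls,
        train_recordings: list[Recording],
        val_recordings: list[Recording],
        stride: int = 1000,
        config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "FetalQRSDetector":
        """Window the recordings (non-overlapping by default) and build the
        model from the resulting labeled windows."""
        tw = [w for r in train_recordings for w in extract_windows(r, stride)]
        vw = [w for r in val_recordings for w in extract_windows(r, stride)]
        return cls(tw, vw, config=config, train_config=train_config)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "FetalQRSResults":
        """Train the detector and return the best-validation-F1 fit."""
        tc = self.train_config
        if seed is not None:
            tc = TrainConfig(**{**tc.__dict__, "seed": seed})
        net = build_network(self.config, seed=tc.seed)
        result = train(net, self.train_data, self.val_data, tc, verbose=verbose)
        return FetalQRSResults(self, net, result)


class FetalQRSResults:
    """A fitted detector: selected weights, history and diagnostics."""

    def __init__(self, model: FetalQRSDetector, network: OctResNet, result: TrainResult):
        self.model = model
        self.network = network
        self.result = result
        self.history = result.history

    # -- inference ---------------------------------------------------------
    def predict(self, window: np.ndarray) -> FramePredictions:
        """Per-frame probability pairs for one 4 x 1000 window."""
        from .data_windows import standardize_windows

        x = window
        if self.model.train_config.normalize:
            x = standardize_windows(window[None])[0]
        return self.network.predict_window(x)

    def evaluate(self, data=None) -> MetricsReport:
        """Frame-level precision/recall/F1 (defaults to validation data)."""
        data = self.model.val_data if data is None else data
        return evaluate(self.network, data, normalize=self.model.train_config.normalize)

    def explain(self, window: np.ndarray, frame: int, target_class: int = 1) -> AttentionMap:
        """Grad-CAM attention trace for one frame decision."""
        return grad_cam(
            window,
            self.network,
            frame,
            target_class,
            normalize=self.model.train_config.normalize,
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        cost = network_cost(cfg)
        val = self.evaluate()
        lines = [
            "Fetal QRS detector fit",
            "=" * 52,
            f"octave ratio alpha          {cfg.alpha:.2f}",
            f"parameters                  {cost.total_params / 1e6:.2f} M",
            f"trunk compute               {cost.total_flops / 1e9:.2f} GFLOPs/window",
            f"recurrent head compute      {cost.gru_fc_flops / 1e9:.4f} GFLOPs/window",
            f"epochs run                  {len(self.history)}",
            f"best epoch (val F1)         {self.result.best_epoch}",
            f"validation F1               {val.f1:.3f}",
            f"validation precision        {val.precision:.3f}",
            f"validation recall           {val.recall:.3f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.network,
            extra={
                "history": self.history,
                "best_epoch": self.result.best_epoch,
                "best_val_f1": self.result.best_val_f1,
                "normalize": self.model.train_config.normalize,
            },
        )

    @classmethod
    def load(cls, path) -> "FetalQRSResults":
        net, extra = load_checkpoint(path)
        tc = TrainConfig(normalize=extra.get("normalize", True))
        model = FetalQRSDetector([], [], config=net.config, train_config=tc)
        result = TrainResult(
            history=extra.get("history", []),
            best_epoch=extra.get("best_epoch", -1),
            best_val_f1=extra.get("best_val_f1", float("nan")),
        )
        return cls(model, net, result)
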
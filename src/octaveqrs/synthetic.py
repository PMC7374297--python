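"""Seedable synthetic 4-channel abdominal f/mECG generator.

Emulates the statistical structure the detector assumes: a dominant
maternal beat train (60-90 bpm), a weaker and faster fetal beat train
(110-160 bpm), per-channel linear mixing of the two sources, and additive
Gaussian sensor noise, with exact ground-truth fetal R-peak sample indices.
Each beat is rendered as a sum of five Gaussian bumps (P, Q, R, S, T waves)
at fixed offsets relative to the R peak, so the mixture contains both slow
(P/T) and sharp (QRS) components.

This is a phenomenological surrogate for clinical abdominal recordings: it
reproduces amplitudes, rates and spectra at the level the detector consumes,
not the electrophysiology (no volume conduction, fetal movement or vernix
attenuation; maternal and fetal rhythms are independent)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_windows import Recording

__all__ = [
    "SynthConfig",
    "MORPHOLOGY",
    "generate_beat_train",
    "render_ecg",
    "generate_recording",
]

# Gaussian bump morphology per beat: (offset_s, width_s, relative_amplitude)
# relative to the R peak with unit R amplitude.  Offsets/widths are typical
# adult surface-ECG values; the fetal template reuses them time-compressed.
MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "P": (-0.200, 0.040, 0.15),
    "Q": (-0.035, 0.010, -0.12),
    "R": (0.000, 0.012, 1.00),
    "S": (0.035, 0.010, -0.25),
    "T": (0.250, 0.070, 0.30),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic abdominal recording.

    Amplitudes are in microvolts.  ``fetal_amplitude_ratio`` scales the
    fetal R amplitude relative to the maternal one before mixing; values
    well below 1 reproduce the clinical situation where the maternal ECG is
    the predominant interference source.
    """

    duration: float = 60.0
    sampling_rate: int = 1000
    maternal_hr_range: tuple[float, float] = (60.0, 90.0)
    fetal_hr_range: tuple[float, float] = (110.0, 160.0)
    rr_jitter_cv: float = 0.02
    maternal_amplitude: float = 25.0
    fetal_amplitude_ratio: float = 0.2
    fetal_time_scale: float = 0.6  # fetal beats are time-compressed copies
    channel_gain_range: tuple[float, float] = (0.5, 1.0)
    channel_gains: tuple | None = None  # explicit (n_channels, 2) mixing matrix
    noise_sd: float = 1.0
    n_channels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer sample count")
        if not 0 < self.fetal_amplitude_ratio <= 1:
            raise ValueError("fetal_amplitude_ratio must lie in (0, 1]")

    @property
    def num_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def generate_beat_train(
    mean_hr: float,
    jitter_cv: float,
    duration: float,
    seed,
    sampling_rate: int = 1000,
) -> np.ndarray:
    """R-peak sample indices of a quasi-periodic beat train.

    RR intervals are ``60 / mean_hr`` seconds with multiplicative Gaussian
    jitter of coefficient-of-variation ``jitter_cv``, truncated to +/-20%
    of the mean interval.  Deterministic per seed.
    """
    if mean_hr <= 0:
        raise ValueError("mean_hr must be positive")
    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / mean_hr
    n_max = int(np.ceil(duration / (0.8 * mean_rr))) + 2
    factors = 1.0 + jitter_cv * rng.standard_normal(n_max)
    rr = mean_rr * np.clip(factors, 0.8, 1.2)
    times = np.cumsum(rr)
    times = times[times < duration]
    idx = np.round(times * sampling_rate).astype(np.int64)
    return idx[idx < int(round(duration * sampling_rate))]


def render_ecg(
    peaks: np.ndarray,
    amplitude: float,
    num_samples: int,
    sampling_rate: int = 1000,
    time_scale: float = 1.0,
    morphology: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Render a single-channel ECG from R-peak indices.

    Each beat adds the five morphology bumps scaled by ``amplitude``;
    ``time_scale`` < 1 compresses the template (fetal beats).  Overlapping
    beats simply sum.
    """
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing")
    morph = morphology or MORPHOLOGY
    signal = np.zeros(num_samples)
    for offset_s, width_s, rel in morph.values():
        offset = offset_s * time_scale * sampling_rate
        width = max(width_s * time_scale * sampling_rate, 1.0)
        half = int(np.ceil(4 * width))
        t = np.arange(-half, half + 1)
        bump = rel * amplitude * np.exp(-0.5 * ((t - 0) / width) ** 2)
        for p in peaks:
            center = int(round(p + offset))
            lo, hi = center - half, center + half + 1
            s_lo, s_hi = max(lo, 0), min(hi, num_samples)
            if s_lo >= s_hi:
                continue
            signal[s_lo:s_hi] += bump[s_lo - lo : s_hi - lo]
    return signal


def generate_recording(config: SynthConfig, record_id: str | None = None) -> Recording:
    """Generate one multi-channel abdominal recording with ground truth.

    Channel i is ``g_m[i] * maternal + g_f[i] * ratio * fetal + noise``;
    the recording's fQRS annotations are the fetal R-peak indices.
    """
    rng = np.random.default_rng(config.seed)
    fs, n = config.sampling_rate, config.num_samples
    maternal_hr = rng.uniform(*config.maternal_hr_range)
    fetal_hr = rng.uniform(*config.fetal_hr_range)
    m_peaks = generate_beat_train(
        maternal_hr, config.rr_jitter_cv, config.duration, rng.integers(2**31), fs
    )
    f_peaks = generate_beat_train(
        fetal_hr, config.rr_jitter_cv, config.duration, rng.integers(2**31), fs
    )
    maternal = render_ecg(m_peaks, config.maternal_amplitude, n, fs, time_scale=1.0)
    fetal = render_ecg(
        f_peaks,
        config.maternal_amplitude * config.fetal_amplitude_ratio,
        n,
        fs,
        time_scale=config.fetal_time_scale,
    )
    if config.channel_gains is not None:
        gains = np.asarray(config.channel_gains, dtype=float)
        if gains.shape != (config.n_channels, 2):
            raise ValueError(f"channel_gains must have shape ({config.n_channels}, 2)")
    else:
        lo, hi = config.channel_gain_range
        gains = rng.uniform(lo, hi, size=(config.n_channels, 2))
    signals = np.empty((config.n_channels, n))
    for i in range(config.n_channels):
        signals[i] = gains[i, 0] * maternal + gains[i, 1] * fetal
    signals += config.noise_sd * rng.standard_normal(signals.shape)
    return Recording(
        signals=signals,
        fqrs_annotations=f_peaks,
        record_id=record_id or f"synth{config.seed:05d}",
        sampling_rate=fs,
        meta={
            "maternal_hr": float(maternal_hr),
            "fetal_hr": float(fetal_hr),
            "maternal_peaks": m_peaks.tolist(),
        },
    )
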
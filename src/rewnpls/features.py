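"""Time-frequency feature extraction for multichannel neural recordings.

Raw signals (e.g. 1 kHz ECoG or MEG voltage traces) are cut into sliding
epochs and mapped to frequency × time × channel feature slabs: each epoch
is transformed with a complex Morlet continuous wavelet transform, the
coefficient moduli are averaged within contiguous equal temporal bins
(decimation), and the per-epoch slabs are stacked into the observation
tensor consumed by the estimator.

With the standard ECoG configuration — 1 s epochs stepped every 100 ms,
analysis frequencies 10…150 Hz in 10 Hz steps, ten 100 ms temporal bins —
a 64-channel recording yields 15 × 10 × 64 slabs; the MEG configuration
(5…100 Hz in 5 Hz steps, 306 channels) yields 20 × 10 × 306.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "EpochConfig",
    "ecog_config",
    "meg_config",
    "morlet_power",
    "epoch_features",
    "epoch_end_times",
    "n_epochs",
]


@dataclass(frozen=True)
class EpochConfig:
    """Epoching and wavelet parameters.

    ``morlet_width`` is the width of the Gaussian envelope in cycles of
    the analysis frequency (the usual neurophysiology parameterization:
    σ_t = width / (2π·f)); 7 cycles is the common default and trades
    temporal against spectral resolution.
    """

    fs: float
    freqs: tuple[float, ...]
    epoch_seconds: float = 1.0
    step_seconds: float = 0.1
    n_time_bins: int = 10
    morlet_width: float = 7.0

    def __post_init__(self):
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        es = self.epoch_seconds * self.fs
        if abs(es - round(es)) > 1e-9:
            raise ValueError("epoch_seconds * fs must be an integer sample count")
        if round(es) % self.n_time_bins:
            raise ValueError(
                f"n_time_bins={self.n_time_bins} must divide the "
                f"{round(es)}-sample epoch"
            )
        if any(f2 <= f1 for f1, f2 in zip(self.freqs, self.freqs[1:])):
            raise ValueError("analysis frequencies must be strictly increasing")
        if not self.freqs or self.freqs[0] <= 0 or self.freqs[-1] >= self.fs / 2:
            raise ValueError("frequencies must lie in (0, fs/2)")

    @property
    def epoch_samples(self) -> int:
        return round(self.epoch_seconds * self.fs)

    @property
    def step_samples(self) -> int:
        return max(1, round(self.step_seconds * self.fs))

    @property
    def wavelet(self) -> str:
        # map "width in cycles" to the pywt cmorB-C parameterization with
        # center frequency C = 1: sigma_t = scale*sqrt(B/2)/fs and
        # f = fs/scale  =>  B = width^2 / (2*pi^2)
        bandwidth = self.morlet_width**2 / (2.0 * np.pi**2)
        return f"cmor{bandwidth:.8f}-1.0"

    @property
    def scales(self) -> np.ndarray:
        return self.fs / np.asarray(self.freqs)


def ecog_config(fs: float = 1000.0, **kwargs) -> EpochConfig:
    """10–150 Hz in 10 Hz steps — the ECoG band configuration."""
    return EpochConfig(fs=fs, freqs=tuple(np.arange(10.0, 151.0, 10.0)), **kwargs)


def meg_config(fs: float = 1000.0, **kwargs) -> EpochConfig:
    """5–100 Hz in 5 Hz steps — the MEG band configuration."""
    return EpochConfig(fs=fs, freqs=tuple(np.arange(5.0, 101.0, 5.0)), **kwargs)


def morlet_power(signal: np.ndarray, cfg: EpochConfig) -> np.ndarray:
    """|CWT| of one channel at the analysis frequencies.

    Returns a ``len(freqs) × n_samples`` nonnegative matrix of complex
    Morlet coefficient moduli, rows ordered as ``cfg.freqs``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("morlet_power expects a single-channel 1-D signal")
    coefs, _ = pywt.cwt(
        signal, cfg.scales, cfg.wavelet, sampling_period=1.0 / cfg.fs, method="fft"
    )
    return np.abs(coefs)


def n_epochs(n_samples: int, cfg: EpochConfig) -> int:
    """floor((T − epoch)/step) + 1 sliding epochs fit in ``n_samples``."""
    return (n_samples - cfg.epoch_samples) // cfg.step_samples + 1


def epoch_end_times(n_samples: int, cfg: EpochConfig) -> np.ndarray:
    """End time (s) of each epoch — the causal alignment point for labels.

    A supervised response Y(t) paired with an epoch is taken at the
    epoch's end so the decoder never sees the future.
    """
    n = n_epochs(n_samples, cfg)
    starts = np.arange(n) * cfg.step_samples
    return (starts + cfg.epoch_samples) / cfg.fs


def epoch_features(signals: np.ndarray, cfg: EpochConfig) -> np.ndarray:
    """Map a channels × samples array to an N × freq × time × channel tensor.

    The CWT modulus is computed once per channel over the full recording,
    sliced into epochs starting every ``step_seconds``, and averaged in
    ``n_time_bins`` contiguous non-overlapping temporal bins per epoch.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if n_samp < cfg.epoch_samples:
        raise ValueError(
            f"need at least {cfg.epoch_samples} samples for one epoch, got {n_samp}"
        )
    n_ep = n_epochs(n_samp, cfg)
    n_freq = len(cfg.freqs)
    bin_len = cfg.epoch_samples // cfg.n_time_bins
    out = np.empty((n_ep, n_freq, cfg.n_time_bins, n_ch))
    for ch in range(n_ch):
        power = morlet_power(signals[ch], cfg)
        for k in range(n_ep):
            start = k * cfg.step_samples
            seg = power[:, start : start + cfg.epoch_samples]
            out[k, :, :, ch] = seg.reshape(n_freq, cfg.n_time_bins, bin_len).mean(
                axis=2
            )
    return out
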
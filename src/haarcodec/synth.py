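"""Synthetic ECG- and EEG-like signal generators.

These generators exist so that the codec can be exercised end-to-end on
signals with realistic morphology without downloading any recordings.
The ECG model sums five Gaussian bumps per beat — the P, Q, R, S and T
deflections at fixed phase offsets from the beat centre — plus white
noise; it is transparent and its R-peak count is exactly testable.  The
EEG model sums sinusoidal band components (e.g. a 10 Hz alpha rhythm) on
top of 1/f^beta Gaussian noise, the canonical spectral shape of scalp
EEG background activity.

Default configurations mirror the common public corpora: 360 Hz sampling
for ECG (``mitbih_like``) and 160 Hz for EEG (``eegmmi_like``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (amplitude, offset from beat centre as a fraction of the beat period,
#:  width in seconds) for the P, Q, R, S, T deflections.
_DEFAULT_WAVES = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.030, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.25, 0.030, 0.010),
    "T": (0.35, 0.30, 0.060),
}


@dataclass
class EcgSynthConfig:
    duration_s: float = 10.0
    sampling_rate_hz: float = 360.0
    heart_rate_bpm: float = 60.0
    waves: dict = field(default_factory=lambda: dict(_DEFAULT_WAVES))
    noise_std: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class EegSynthConfig:
    duration_s: float = 10.0
    sampling_rate_hz: float = 160.0
    #: sequence of (centre frequency in Hz, amplitude) sinusoids
    components: tuple = ((10.0, 1.0), (20.0, 0.3))
    noise_exponent: float = 1.0
    noise_scale: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        for freq, _amp in self.components:
            if freq >= self.sampling_rate_hz / 2.0:
                raise ValueError(
                    f"component frequency {freq} Hz is at or above Nyquist "
                    f"({self.sampling_rate_hz / 2.0} Hz)"
                )
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


def generate_ecg(config: EcgSynthConfig) -> np.ndarray:
    """Generate a deterministic ECG-like trace of length duration*rate."""
    n = int(config.duration_s * config.sampling_rate_hz)
    t = np.arange(n) / config.sampling_rate_hz
    period = 60.0 / config.heart_rate_bpm
    signal = np.zeros(n)
    # beat centres at (k + 1/2) * period so R peaks are interior maxima
    n_beats = int(np.ceil(config.duration_s / period)) + 1
    for k in range(n_beats):
        centre = (k + 0.5) * period
        for amp, frac_offset, width in config.waves.values():
            mu = centre + frac_offset * period
            signal += amp * np.exp(-0.5 * ((t - mu) / width) ** 2)
    if config.noise_std > 0:
        rng = np.random.default_rng(config.rng_seed)
        signal = signal + rng.normal(0.0, config.noise_std, size=n)
    return signal


def _one_over_f_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit std."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    std = shaped.std()
    return shaped / std if std > 0 else shaped


def generate_eeg(config: EegSynthConfig) -> np.ndarray:
    """Generate a deterministic EEG-like trace: band sinusoids + 1/f noise."""
    n = int(config.duration_s * config.sampling_rate_hz)
    t = np.arange(n) / config.sampling_rate_hz
    signal = np.zeros(n)
    for freq, amp in config.components:
        signal += amp * np.sin(2.0 * np.pi * freq * t)
    if config.noise_scale > 0:
        rng = np.random.default_rng(config.rng_seed)
        signal = signal + config.noise_scale * _one_over_f_noise(
            n, config.noise_exponent, rng
        )
    return signal


def mitbih_like(duration_s: float = 10.0, rng_seed: int = 42) -> EcgSynthConfig:
    """ECG defaults matching the common arrhythmia corpus: 360 Hz sampling."""
    return EcgSynthConfig(
        duration_s=duration_s, sampling_rate_hz=360.0, rng_seed=rng_seed
    )


def eegmmi_like(duration_s: float = 10.0, rng_seed: int = 42) -> EegSynthConfig:
    """EEG defaults matching the motor movement/imagery corpus: 160 Hz."""
    return EegSynthConfig(
        duration_s=duration_s, sampling_rate_hz=160.0, rng_seed=rng_seed
    )
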
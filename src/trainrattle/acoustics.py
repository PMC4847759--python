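"""Bioacoustics of the mechanical rattle sound.

The display produces short broadband sound pulses, one per feather
vibration cycle, so the pulse repetition rate of the audio equals the
feather vibration frequency seen on video.  Spectrograms use a Hann window
with a 0.01 s short-time window (86.1 Hz frequency resolution at 44.1 kHz
with a power-of-two DFT) and 95% overlap; power spectra use a 1.00 s window
for 1 Hz resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import AudioClip

__all__ = [
    "SpectrogramConfig",
    "spectrogram",
    "spectrogram_resolution",
    "power_spectrum",
    "pulse_envelope",
    "detect_pulses",
    "pulse_rate",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """Short-time Fourier transform parameters for audio analysis."""

    window: str = "hann"
    window_dur: float = 0.01  # s
    overlap: float = 0.95  # fraction of the window
    dft_size_rule: str = "next_pow2"  # or "exact"

    def __post_init__(self) -> None:
        if self.window != "hann":
            raise ValueError("only the Hann window is supported")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_dur <= 0:
            raise ValueError("window_dur must be positive")
        if self.dft_size_rule not in ("next_pow2", "exact"):
            raise ValueError("dft_size_rule must be 'next_pow2' or 'exact'")

    def n_window(self, fs: float) -> int:
        return int(round(self.window_dur * fs))

    def n_fft(self, fs: float) -> int:
        n = self.n_window(fs)
        if self.dft_size_rule == "exact":
            return n
        return int(2 ** math.ceil(math.log2(n)))


POWER_SPECTRUM_CONFIG = SpectrogramConfig(window_dur=1.00, dft_size_rule="exact")


def spectrogram_resolution(config: SpectrogramConfig, fs: float) -> float:
    """Frequency bin spacing (Hz) of the configured spectrogram: fs / N_DFT."""
    return fs / config.n_fft(fs)


def spectrogram(
    clip: AudioClip, config: SpectrogramConfig = SpectrogramConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude grid of an audio clip.

    Returns ``(frequencies, times, magnitude)`` with magnitude shaped
    ``(n_freq, n_time)``.
    """
    if clip.samples.size == 0:
        raise ValueError("empty audio clip")
    nper = config.n_window(clip.fs)
    if nper > clip.samples.size:
        raise ValueError("window longer than the clip")
    nover = int(math.floor(config.overlap * nper))
    f, t, z = signal.stft(
        clip.samples,
        fs=clip.fs,
        window="hann",
        nperseg=nper,
        noverlap=nover,
        nfft=config.n_fft(clip.fs),
        boundary=None,
        padded=False,
    )
    return f, t, np.abs(z)


def power_spectrum(
    clip: AudioClip, config: SpectrogramConfig = POWER_SPECTRUM_CONFIG
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectrum with the configured window (default 1 s, 1 Hz)."""
    nper = config.n_window(clip.fs)
    if nper > clip.samples.size:
        raise ValueError("window longer than the clip")
    f, p = signal.welch(
        clip.samples,
        fs=clip.fs,
        window="hann",
        nperseg=nper,
        noverlap=int(math.floor(config.overlap * nper)),
        nfft=config.n_fft(clip.fs),
    )
    return f, p


def pulse_envelope(clip: AudioClip, cutoff_hz: float = 100.0) -> np.ndarray:
    """Amplitude envelope: rectify, then 4th-order Butterworth low-pass."""
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=clip.fs, output="sos")
    return np.clip(signal.sosfiltfilt(sos, np.abs(clip.samples)), 0.0, None)


def detect_pulses(
    clip: AudioClip,
    cutoff_hz: float = 100.0,
    max_rate_hz: float = 50.0,
    rel_height: float = 0.3,
) -> np.ndarray:
    """Sample indices of rattle pulses from the amplitude envelope.

    Peak picking with a refractory period of ``1/max_rate_hz`` and a
    height threshold relative to the strongest pulse; gain-invariant.
    """
    env = pulse_envelope(clip, cutoff_hz)
    if np.max(env) <= 0:
        return np.array([], dtype=int)
    distance = max(int(round(clip.fs / max_rate_hz)), 1)
    idx, _ = signal.find_peaks(
        env, distance=distance, height=rel_height * float(np.max(env)),
        prominence=0.5 * rel_height * float(np.max(env)),
    )
    return idx


def pulse_rate(clip: AudioClip, min_pulses: int = 10, **kwargs) -> float:
    """Pulse repetition rate (Hz) of the rattle sound.

    Rate is ``(n_peaks - 1) / span`` over the detected pulse train; this is
    the audio-side estimate of the feather vibration frequency.
    """
    idx = detect_pulses(clip, **kwargs)
    if idx.size < min_pulses:
        raise ValueError(
            f"only {idx.size} pulses detected; need >= {min_pulses} for a rate"
        )
    span = (idx[-1] - idx[0]) / clip.fs
    return float((idx.size - 1) / span)
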
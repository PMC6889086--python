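"""Core audio containers.

The whole algorithm operates on two in-memory types: a monaural
:class:`AudioSignal` (a 1-D float array plus a sample rate) and a
:class:`BinauralSignal` (a left/right pair sharing length and rate).
WAV round-tripping goes through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 40_000


@dataclass
class AudioSignal:
    """A single-channel waveform with dimensionless amplitude.

    Parameters
    ----------
    samples : ndarray
        1-D float array. Values must be finite.
    sample_rate : int
        Sampling rate in Hz, default 40 kHz.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2))) if len(self.samples) else 0.0

    def scaled(self, gain: float) -> "AudioSignal":
        return AudioSignal(self.samples * gain, self.sample_rate)

    def padded_to(self, n_samples: int) -> "AudioSignal":
        if len(self.samples) >= n_samples:
            return self
        out = np.zeros(n_samples)
        out[: len(self.samples)] = self.samples
        return AudioSignal(out, self.sample_rate)


@dataclass
class BinauralSignal:
    """Left/right ear waveform pair with shared length and sample rate."""

    left: AudioSignal
    right: AudioSignal

    def __post_init__(self) -> None:
        if len(self.left.samples) != len(self.right.samples):
            raise ValueError("left/right lengths differ")
        if self.left.sample_rate != self.right.sample_rate:
            raise ValueError("left/right sample rates differ")

    @property
    def sample_rate(self) -> int:
        return self.left.sample_rate

    @property
    def duration(self) -> float:
        return self.left.duration

    def __add__(self, other: "BinauralSignal") -> "BinauralSignal":
        if self.sample_rate != other.sample_rate:
            raise ValueError("sample rates differ")
        n = max(len(self.left.samples), len(other.left.samples))
        return BinauralSignal(
            AudioSignal(
                self.left.padded_to(n).samples + other.left.padded_to(n).samples,
                self.sample_rate,
            ),
            AudioSignal(
                self.right.padded_to(n).samples + other.right.padded_to(n).samples,
                self.sample_rate,
            ),
        )


def read_wav(path: str | Path) -> AudioSignal | BinauralSignal:
    """Read a PCM or float WAV file; stereo files become BinauralSignal."""
    rate, data = wavfile.read(str(path))
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 1:
        return AudioSignal(data, rate)
    return BinauralSignal(AudioSignal(data[:, 0], rate), AudioSignal(data[:, 1], rate))


def write_wav(path: str | Path, signal: AudioSignal | BinauralSignal) -> None:
    """Write as 32-bit float WAV."""
    if isinstance(signal, BinauralSignal):
        data = np.stack([signal.left.samples, signal.right.samples], axis=1)
        rate = signal.sample_rate
    else:
        data = signal.samples
        rate = signal.sample_rate
    wavfile.write(str(path), rate, data.astype(np.float32))
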
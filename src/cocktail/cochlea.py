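"""Gammatone cochlear filterbank and envelope extraction.

Each ear signal is decomposed into 36 ERB-spaced 4th-order gammatone
channels with center frequencies from 300 to 5000 Hz.  Channel envelopes are
the magnitude of the analytic signal, lowpassed at 400 Hz — the standard
vocoder notion of an envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import butter, gammatone, hilbert, lfilter, sosfiltfilt

from .signals import AudioSignal

# Glasberg & Moore (1990) ERB constants
_EAR_Q = 9.26449
_MIN_BW = 24.7


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray:
    """Equivalent rectangular bandwidth (Hz) at frequency ``f``."""
    return _MIN_BW + np.asarray(f, dtype=float) / _EAR_Q


def _erb_rate(f: np.ndarray | float) -> np.ndarray:
    """Frequency (Hz) -> ERB-rate (number of ERBs below f)."""
    return _EAR_Q * np.log(1.0 + np.asarray(f, dtype=float) / (_MIN_BW * _EAR_Q))


def _erb_rate_inv(e: np.ndarray) -> np.ndarray:
    return _MIN_BW * _EAR_Q * (np.exp(np.asarray(e, dtype=float) / _EAR_Q) - 1.0)


@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout: 36 channels, 300-5000 Hz, order 4."""

    n_channels: int = 36
    cf_min: float = 300.0
    cf_max: float = 5000.0
    order: int = 4
    sample_rate: int = 40_000

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (0 < self.cf_min < self.cf_max):
            raise ValueError("need 0 < cf_min < cf_max")
        if self.cf_max >= self.sample_rate / 2:
            raise ValueError("cf_max must lie below the Nyquist frequency")


def erb_center_frequencies(spec: FilterbankSpec) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale.

    Endpoints are included: CF_1 = cf_min and CF_n = cf_max.
    """
    if spec.n_channels == 1:
        return np.array([spec.cf_min])
    e = np.linspace(_erb_rate(spec.cf_min), _erb_rate(spec.cf_max), spec.n_channels)
    cfs = _erb_rate_inv(e)
    cfs[0], cfs[-1] = spec.cf_min, spec.cf_max  # pin endpoints exactly
    return cfs


@dataclass
class Cochleagram:
    """Band signals and envelopes, one row per gammatone channel."""

    channels: np.ndarray  # (n_channels, n_samples)
    envelopes: np.ndarray  # same shape, >= 0
    cfs: np.ndarray  # Hz
    sample_rate: int

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


@lru_cache(maxsize=None)
def _filterbank_coeffs(spec: FilterbankSpec):
    cfs = erb_center_frequencies(spec)
    return cfs, [gammatone(cf, "iir", fs=spec.sample_rate) for cf in cfs]


@lru_cache(maxsize=None)
def _env_lowpass(sample_rate: int):
    return butter(4, 400.0, btype="low", fs=sample_rate, output="sos")


def analyze(signal: AudioSignal, spec: FilterbankSpec | None = None) -> Cochleagram:
    """Run a waveform through the gammatone filterbank.

    Returns the per-channel band signals and their envelopes (analytic-signal
    magnitude, lowpassed at 400 Hz, clipped at zero).
    """
    spec = spec or FilterbankSpec()
    if signal.sample_rate != spec.sample_rate:
        raise ValueError("signal sample rate does not match filterbank spec")
    if len(signal.samples) == 0:
        raise ValueError("empty signal")
    cfs, coeffs = _filterbank_coeffs(spec)
    n = len(signal.samples)
    bands = np.empty((spec.n_channels, n))
    for i, (b, a) in enumerate(coeffs):
        bands[i] = lfilter(b, a, signal.samples)
    env = np.abs(hilbert(bands, axis=1))
    sos = _env_lowpass(spec.sample_rate)
    env = sosfiltfilt(sos, env, axis=1)
    np.clip(env, 0.0, None, out=env)
    return Cochleagram(bands, env, cfs, spec.sample_rate)


def analyze_binaural(binaural, spec: FilterbankSpec | None = None):
    """Convenience: analyze both ears with one spec."""
    return analyze(binaural.left, spec), analyze(binaural.right, spec)
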
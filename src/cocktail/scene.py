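"""Synthetic binaural scene generation.

This module stands in for a recorded speech corpus plus measured HRTFs.  It
produces speech-like test sentences (amplitude-modulated harmonic complexes
with slowly moving formant-like spectral peaks), spatializes them with a
parametric spherical-head model (Woodworth ITD + a frequency-dependent ILD
table), and mixes target/masker configurations at controlled
target-to-masker ratios (TMR).

Sign convention (used everywhere in the package): positive azimuth is to the
listener's right; ITD is positive when the right ear leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import firwin2, fftconvolve

from .signals import AudioSignal, BinauralSignal, read_wav

SENTENCE_RMS = 0.05

# default ILD-at-90-degrees table: (frequency Hz, dB); interpolated on log f
_DEFAULT_ILD_TABLE = ((300.0, 0.0), (5000.0, 10.0))


# --------------------------------------------------------------------------
# head model
# --------------------------------------------------------------------------


@dataclass
class HeadModel:
    """Parametric binaural rendering model.

    In ``parametric`` mode the interaural time difference follows the
    Woodworth spherical-head formula ITD = (a/c)(sin θ + θ) and the
    interaural level difference grows linearly in \\|sin θ\\| up to a
    frequency-dependent maximum (0 dB at 300 Hz rising to 10 dB at 5 kHz by
    default).  In ``hrtf_files`` mode measured impulse-response pairs are
    convolved instead.
    """

    head_radius: float = 0.0875  # m
    speed_of_sound: float = 343.0  # m/s
    ild_max_per_freq: tuple = _DEFAULT_ILD_TABLE
    mode: str = "parametric"
    hrtf_dir: str | None = None

    def itd(self, azimuth_deg: float) -> float:
        """ITD in seconds; positive when the right ear leads (azimuth > 0)."""
        theta = np.deg2rad(azimuth_deg)
        return (self.head_radius / self.speed_of_sound) * (np.sin(theta) + theta)

    def ild_max(self, freq_hz: np.ndarray | float) -> np.ndarray:
        """Maximum ILD magnitude (dB) at 90 deg for the given frequencies."""
        f = np.atleast_1d(np.asarray(freq_hz, dtype=float))
        table = np.asarray(self.ild_max_per_freq, dtype=float)
        logf = np.log(np.clip(f, table[0, 0], table[-1, 0]))
        out = np.interp(logf, np.log(table[:, 0]), table[:, 1])
        return out

    def ild_db(self, azimuth_deg: float, freq_hz: np.ndarray | float) -> np.ndarray:
        """Left-minus-right level difference in dB (negative for right side)."""
        theta = np.deg2rad(azimuth_deg)
        return -np.sin(theta) * self.ild_max(freq_hz)


# --------------------------------------------------------------------------
# sentence generator
# --------------------------------------------------------------------------


def generate_sentence(
    seed: int, duration: float = 1.5, f0: float = 120.0, sample_rate: int = 40_000
) -> AudioSignal:
    """Generate a reproducible speech-like sentence.

    The signal is a harmonic complex on a slowly drifting fundamental,
    spectrally shaped by 2-4 formant-like Gaussian peaks whose center
    frequencies wander within 300-5000 Hz, and amplitude-modulated by a
    syllabic (4-8 Hz) envelope.  RMS is normalized to 0.05.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    if not (0.5 <= duration <= 5.0):
        raise ValueError("duration must lie in [0.5, 5] s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    # drifting fundamental: +-4 % excursion on a slow random curve
    knots = rng.normal(0.0, 1.0, 6)
    drift = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, 6), knots)
    f0_t = f0 * (1.0 + 0.04 * drift)

    # formant-like peaks with slowly moving centers (log-uniform in band),
    # each carrying its own syllabic (4-8 Hz) amplitude envelope so band
    # envelopes are not co-modulated the way a single global envelope would be
    n_formants = int(rng.integers(2, 5))
    fmt_lo, fmt_hi = 300.0, 5000.0
    centers, fenvs = [], []
    for _ in range(n_formants):
        a, b = np.exp(rng.uniform(np.log(fmt_lo), np.log(fmt_hi), 2))
        frac = 0.5 - 0.5 * np.cos(np.pi * np.linspace(0, 1, n))  # smooth glide
        centers.append(a * (b / a) ** frac)
        n_knots = max(4, int(duration * rng.uniform(4.0, 8.0)) + 1)
        knots = rng.normal(0.0, 1.0, n_knots)
        z = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, n_knots), knots)
        fenvs.append(0.05 + 0.95 / (1.0 + np.exp(-2.5 * z)))
    centers = np.stack(centers)  # (n_formants, n)
    fenvs = np.stack(fenvs)
    bandwidths = 0.12 * centers + 60.0

    n_harm = max(2, int(fmt_hi / (f0 * 1.04)))
    phase0 = 2 * np.pi * np.cumsum(f0_t) / sample_rate
    wave = np.zeros(n)
    for k in range(1, n_harm + 1):
        fk = k * f0_t
        shape = np.exp(-((fk[None] - centers) ** 2) / (2 * bandwidths**2)) * fenvs
        amp = (np.sum(shape, axis=0) + 0.005) / k**0.3  # floor + gentle tilt
        wave += amp * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))

    # word-like gating: 2-4 bursts separated by brief near-silent pauses
    n_pause = int(rng.integers(1, 4))
    gate = np.ones(n)
    for _ in range(n_pause):
        p0 = rng.uniform(0.1, 0.85) * duration
        p1 = p0 + rng.uniform(0.06, 0.15)
        gate *= 1.0 - 0.98 / (1 + np.exp(-(t - p0) / 0.008)) / (
            1 + np.exp((t - p1) / 0.008)
        )
    ramp = np.minimum(1.0, np.minimum(t, duration - t) / 0.05)  # 50 ms edges
    wave *= gate * ramp

    wave *= SENTENCE_RMS / np.sqrt(np.mean(wave**2))
    return AudioSignal(wave, sample_rate)


# --------------------------------------------------------------------------
# spatialization
# --------------------------------------------------------------------------

_FRAC_TAPS = 64  # windowed-sinc fractional-delay length
_FRAC_BASE = _FRAC_TAPS // 2  # shared integer group delay applied to both ears
_ILD_TAPS = 255


def _fractional_delay_filter(frac: float) -> np.ndarray:
    """64-tap Kaiser-windowed sinc delaying by (_FRAC_BASE + frac) samples."""
    n = np.arange(_FRAC_TAPS)
    h = np.sinc(n - _FRAC_BASE - frac)
    h *= np.kaiser(_FRAC_TAPS, 8.6)
    return h / np.sum(h)


def _delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Delay a waveform by a (possibly fractional) number of samples.

    Every call adds the same _FRAC_BASE-sample latency, so relative delays
    between two ears are exact.
    """
    d_int = int(np.floor(delay_samples))
    frac = delay_samples - d_int
    h = _fractional_delay_filter(frac)
    y = fftconvolve(x, h, mode="full")
    return np.concatenate([np.zeros(d_int), y])


def _ild_filters(head: HeadModel, azimuth_deg: float, sample_rate: int):
    """Linear-phase per-ear FIRs realizing half the ILD in each ear."""
    nyq = sample_rate / 2
    freqs = np.concatenate([[0.0], np.geomspace(100.0, nyq * 0.999, 48), [nyq]])
    ild = head.ild_db(azimuth_deg, freqs)  # left minus right, dB
    g_left = 10.0 ** (ild / 2.0 / 20.0)
    g_right = 10.0 ** (-ild / 2.0 / 20.0)
    # keep mean two-ear power at the input level for every frequency
    norm = np.sqrt(2.0 / (g_left**2 + g_right**2))
    g_left *= norm
    g_right *= norm
    hl = firwin2(_ILD_TAPS, freqs, g_left, fs=sample_rate)
    hr = firwin2(_ILD_TAPS, freqs, g_right, fs=sample_rate)
    return hl, hr


def spatialize(
    signal: AudioSignal, azimuth_deg: float, head: HeadModel | None = None
) -> BinauralSignal:
    """Render a monaural signal at an azimuth as a binaural pair.

    Parametric mode imposes the head model's ITD (windowed-sinc fractional
    delay of the far ear) and per-frequency ILD (split symmetrically between
    ears).  Mean two-ear energy stays within 1 dB of the input energy.
    """
    head = head or HeadModel()
    if not (-90.0 <= azimuth_deg <= 90.0):
        raise ValueError("azimuth must lie in [-90, 90] degrees")

    if head.mode == "hrtf_files":
        return _spatialize_hrtf(signal, azimuth_deg, head)

    itd_samples = abs(head.itd(azimuth_deg)) * signal.sample_rate
    x = signal.samples
    near = _delay(x, 0.0)
    far = _delay(x, itd_samples)
    n = max(len(near), len(far))
    near = np.concatenate([near, np.zeros(n - len(near))])
    far = np.concatenate([far, np.zeros(n - len(far))])

    hl, hr = _ild_filters(head, azimuth_deg, signal.sample_rate)
    if azimuth_deg >= 0:  # source on the right: right ear near/loud
        left, right = far, near
    else:
        left, right = near, far
    left = fftconvolve(left, hl, mode="full")
    right = fftconvolve(right, hr, mode="full")
    return BinauralSignal(
        AudioSignal(left, signal.sample_rate), AudioSignal(right, signal.sample_rate)
    )


def _spatialize_hrtf(
    signal: AudioSignal, azimuth_deg: float, head: HeadModel
) -> BinauralSignal:
    """Convolve with a measured HRTF pair ``az{+NN}_L.wav`` / ``_R.wav``."""
    if head.hrtf_dir is None:
        raise ValueError("hrtf_files mode requires hrtf_dir")
    az = int(round(azimuth_deg))
    stem = Path(head.hrtf_dir) / f"az{az:+03d}"
    lpath, rpath = Path(f"{stem}_L.wav"), Path(f"{stem}_R.wav")
    if not (lpath.exists() and rpath.exists()):
        raise FileNotFoundError(f"missing HRTF pair for azimuth {az}: {lpath}")
    hl = read_wav(lpath)
    hr = read_wav(rpath)
    left = fftconvolve(signal.samples, hl.samples, mode="full")
    right = fftconvolve(signal.samples, hr.samples, mode="full")
    # normalize so mean two-ear energy matches the input energy
    e_in = np.sum(signal.samples**2)
    e_out = 0.5 * (np.sum(left**2) + np.sum(right**2))
    g = np.sqrt(e_in / e_out) if e_out > 0 else 1.0
    return BinauralSignal(
        AudioSignal(left * g, signal.sample_rate),
        AudioSignal(right * g, signal.sample_rate),
    )


# --------------------------------------------------------------------------
# scene mixing
# --------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """A target plus maskers, each with an azimuth, and a TMR in dB.

    TMR applies between the target and EACH masker individually (pre-
    spatialization mono energies), regardless of the number of maskers.
    """

    target: tuple[AudioSignal, float]
    maskers: list[tuple[AudioSignal, float]] = field(default_factory=list)
    tmr_db: float = 0.0

    def __post_init__(self) -> None:
        for _, az in [self.target, *self.maskers]:
            if not (-90.0 <= az <= 90.0):
                raise ValueError("azimuth must lie in [-90, 90] degrees")


def mix_scene(spec: SceneSpec, head: HeadModel | None = None) -> BinauralSignal:
    """Scale, spatialize and sum all sources of a scene.

    Each masker is rescaled (before spatialization) so that
    10*log10(E_target / E_masker) equals ``tmr_db``; shorter sources are
    zero-padded to the longest.
    """
    head = head or HeadModel()
    target_sig, target_az = spec.target
    rates = {target_sig.sample_rate} | {s.sample_rate for s, _ in spec.maskers}
    if len(rates) != 1:
        raise ValueError("all sources must share one sample rate")

    e_target = np.sum(target_sig.samples**2)
    out = spatialize(target_sig, target_az, head)
    for masker_sig, masker_az in spec.maskers:
        e_m = np.sum(masker_sig.samples**2)
        if e_m == 0:
            raise ValueError("masker is silent")
        gain = np.sqrt(e_target / e_m * 10.0 ** (-spec.tmr_db / 10.0))
        out = out + spatialize(masker_sig.scaled(gain), masker_az, head)
    return out
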
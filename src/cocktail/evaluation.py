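"""Objective intelligibility and segregation metrics.

Implements the short-time objective intelligibility measure (STOI) from its
published definition (Taal et al., 2011): resampling to 10 kHz, removal of
silent frames, a third-octave band decomposition (15 bands from 150 Hz), and
clipped, normalized short-time (384 ms) envelope correlations averaged over
bands and segments.  On top of it: the logistic mapping from STOI to
predicted percent-correct intelligibility, the target-vs-masker score
difference (delta STOI) used to quantify segregation, and the 50 %
target-to-masker-ratio threshold for psychometric comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .signals import AudioSignal

STOI_FS = 10_000
_FRAME = 256
_HOP = 128
_NFFT = 512
_N_BANDS = 15
_FIRST_CF = 150.0
_SEG = 30  # frames per 384 ms segment
_DYN_RANGE_DB = 40.0
_CLIP_DB = -15.0

# logistic map from STOI to percent words correct
_LOGISTIC_A = 13.1903
_LOGISTIC_B = 6.5192


def _third_octave_matrix(fs: int = STOI_FS, nfft: int = _NFFT) -> np.ndarray:
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    cfs = _FIRST_CF * 2.0 ** (np.arange(_N_BANDS) / 3.0)
    lo = cfs * 2.0 ** (-1.0 / 6.0)
    hi = cfs * 2.0 ** (1.0 / 6.0)
    mat = (freqs[None, :] >= lo[:, None]) & (freqs[None, :] < hi[:, None])
    return mat.astype(np.float64)


def _frames(x: np.ndarray, window: np.ndarray) -> np.ndarray:
    n = (len(x) - _FRAME) // _HOP + 1
    if n < 1:
        return np.empty((0, _FRAME))
    idx = np.arange(_FRAME)[None, :] + _HOP * np.arange(n)[:, None]
    return x[idx] * window[None, :]


def _remove_silent_frames(x: np.ndarray, y: np.ndarray):
    """Drop frames whose reference energy is > 40 dB below the loudest frame."""
    w = np.hanning(_FRAME + 2)[1:-1]
    fx = _frames(x, w)
    fy = _frames(y, w)
    if len(fx) == 0:
        return x, y
    energy = 20.0 * np.log10(np.linalg.norm(fx, axis=1) + 1e-12)
    keep = energy > np.max(energy) - _DYN_RANGE_DB
    fx, fy = fx[keep], fy[keep]
    n_out = (len(fx) - 1) * _HOP + _FRAME if len(fx) else 0
    xs = np.zeros(n_out)
    ys = np.zeros(n_out)
    norm = np.zeros(n_out)
    for i in range(len(fx)):  # overlap-add
        sl = slice(i * _HOP, i * _HOP + _FRAME)
        xs[sl] += fx[i]
        ys[sl] += fy[i]
        norm[sl] += w
    norm[norm == 0] = 1.0
    return xs / norm, ys / norm


def _band_envelopes(x: np.ndarray, band_matrix: np.ndarray) -> np.ndarray:
    w = np.hanning(_FRAME + 2)[1:-1]
    fx = _frames(x, w)
    spec = np.abs(np.fft.rfft(fx, _NFFT, axis=1)) ** 2  # (frames, bins)
    return np.sqrt(band_matrix @ spec.T)  # (bands, frames)


def compute_stoi(reference: AudioSignal, processed: AudioSignal) -> float:
    """STOI of ``processed`` against ``reference``, in [0, 1] (approximately).

    Both signals are trimmed to the shorter one and resampled to 10 kHz.
    Raises for signals shorter than 1 s, where the measure is undefined.
    """
    if reference.sample_rate != processed.sample_rate:
        raise ValueError("signals must share a sample rate")
    n = min(len(reference.samples), len(processed.samples))
    if n / reference.sample_rate < 1.0:
        raise ValueError("STOI requires at least 1 s of signal")
    x = reference.samples[:n]
    y = processed.samples[:n]
    fs = reference.sample_rate
    if fs != STOI_FS:
        g = np.gcd(fs, STOI_FS)
        x = resample_poly(x, STOI_FS // g, fs // g)
        y = resample_poly(y, STOI_FS // g, fs // g)

    x, y = _remove_silent_frames(x, y)
    band = _third_octave_matrix()
    ex = _band_envelopes(x, band)  # (bands, frames)
    ey = _band_envelopes(y, band)
    n_frames = ex.shape[1]
    if n_frames < _SEG:
        raise ValueError("too little active signal for STOI")

    clip_gain = 10.0 ** (-_CLIP_DB / 20.0)  # beta = -15 dB lower SDR bound
    scores = []
    for m in range(_SEG, n_frames + 1):
        xs = ex[:, m - _SEG : m]
        ys = ey[:, m - _SEG : m]
        alpha = np.linalg.norm(xs, axis=1, keepdims=True) / (
            np.linalg.norm(ys, axis=1, keepdims=True) + 1e-12
        )
        ys_n = np.minimum(ys * alpha, xs * (1.0 + clip_gain))
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys_n - ys_n.mean(axis=1, keepdims=True)
        num = np.sum(xs_c * ys_c, axis=1)
        den = np.linalg.norm(xs_c, axis=1) * np.linalg.norm(ys_c, axis=1) + 1e-12
        scores.append(num / den)
    return float(np.mean(scores))


def predicted_intelligibility(stoi: float) -> float:
    """Percent words correct predicted from a STOI score via the logistic map

    100 / (1 + exp(-13.1903 * STOI + 6.5192)).
    """
    if not (0.0 <= stoi <= 1.0):
        raise ValueError("STOI must lie in [0, 1]")
    return 100.0 / (1.0 + np.exp(-_LOGISTIC_A * stoi + _LOGISTIC_B))


@dataclass
class EvaluationRecord:
    """STOI against target and maskers, their difference, and predicted %."""

    stoi_vs_target: float
    stoi_vs_maskers: list = field(default_factory=list)
    delta_stoi: float | None = None
    predicted_intelligibility_pct: float = 0.0

    def to_dict(self) -> dict:
        return {
            "stoi_vs_target": self.stoi_vs_target,
            "stoi_vs_maskers": list(self.stoi_vs_maskers),
            "delta_stoi": self.delta_stoi,
            "predicted_intelligibility_pct": self.predicted_intelligibility_pct,
        }


def delta_stoi(
    output: AudioSignal,
    target: AudioSignal,
    maskers: list[AudioSignal],
    reduce: str = "mean",
) -> EvaluationRecord:
    """Segregation record: delta = STOI(output, target) - reduce(STOI(output, maskers)).

    ``reduce`` is "mean" (default) or "max" over the masker-referenced
    scores; the mean keeps delta unbiased when target and maskers are
    spatially indistinguishable.
    """
    s_t = compute_stoi(target, output)
    s_m = [compute_stoi(m, output) for m in maskers]
    delta = None
    if s_m:
        agg = max(s_m) if reduce == "max" else float(np.mean(s_m))
        delta = s_t - agg
    return EvaluationRecord(
        stoi_vs_target=s_t,
        stoi_vs_maskers=s_m,
        delta_stoi=delta,
        predicted_intelligibility_pct=predicted_intelligibility(np.clip(s_t, 0.0, 1.0)),
    )


@dataclass
class PsychometricPoint:
    """50 % TMR threshold at one target/masker separation."""

    separation_deg: float
    tmr_threshold_50: float | None
    unbounded: bool = False


def tmr_threshold_50(
    trials: list[tuple[float, bool]], separation_deg: float = 0.0
) -> PsychometricPoint:
    """Lowest TMR where the target-referenced score wins on >= 50 % of trials.

    ``trials`` holds (tmr_db, target_won) pairs; the win fraction is computed
    per TMR level and the 0.5 crossing is linearly interpolated between
    adjacent levels.  If the fraction never reaches 0.5 the point is flagged
    unbounded.
    """
    trials = list(trials)
    levels = sorted({t for t, _ in trials})
    if len(levels) < 2:
        raise ValueError("need at least two TMR levels")
    frac = []
    for lv in levels:
        wins = [won for t, won in trials if t == lv]
        frac.append(np.mean(wins))
    frac = np.asarray(frac)
    if frac[0] >= 0.5:
        return PsychometricPoint(separation_deg, float(levels[0]))
    for i in range(1, len(levels)):
        if frac[i] >= 0.5:
            t0, t1 = levels[i - 1], levels[i]
            f0, f1 = frac[i - 1], frac[i]
            thr = t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0)
            return PsychometricPoint(separation_deg, float(thr))
    return PsychometricPoint(separation_deg, None, unbounded=True)
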
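"""Linear stimulus reconstruction from cortical spike trains.

Per frequency channel, a linear decoding filter maps the spike train onto
the acoustic envelope of that channel.  The 1-D filter is derived
analytically in the frequency domain, H = S_sx / (S_xx + eps), from Welch
spectral estimates on a clean training stimulus.  The 2-D filter adds an
input-channel dimension (time taps x input channels) and is fine-tuned by
batch gradient descent on the envelope mean-squared error, starting from the
1-D solution placed on its own channel.  Decoded envelopes finally modulate
pure-tone carriers at the channel center frequencies and are summed into the
output waveform.

Filters are 2048 taps (51.2 ms at 40 kHz) and acausal: tap index 1024 is
zero lag, so taps cover lags -25.6..+25.6 ms.  A valid-mode decode of a
T-sample spike matrix yields T - 2047 samples, aligned to stimulus samples
[DECODE_OFFSET, T - N_TAPS + DECODE_OFFSET).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import csd, welch

from .midbrain import SpikeRaster
from .signals import AudioSignal

N_TAPS = 2048
CENTER = N_TAPS // 2  # tap index of zero lag
DECODE_OFFSET = CENTER - 1  # decoded sample k estimates stimulus sample k + offset


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class FilterBank1D:
    """One 2048-tap decoding kernel per frequency channel."""

    taps: np.ndarray  # (n_channels, N_TAPS)
    cfs: np.ndarray
    sample_rate: int
    untrained: np.ndarray | None = None  # bool mask of channels left at zero

    def __post_init__(self) -> None:
        if self.taps.shape[1] != N_TAPS:
            raise ValueError(f"filters must have exactly {N_TAPS} taps")
        if self.untrained is None:
            self.untrained = np.zeros(len(self.taps), dtype=bool)

    def save_npz(self, path) -> None:
        np.savez(
            path,
            taps=self.taps,
            cfs=self.cfs,
            sample_rate=self.sample_rate,
            untrained=self.untrained,
        )

    @classmethod
    def load_npz(cls, path) -> "FilterBank1D":
        d = np.load(path)
        return cls(d["taps"], d["cfs"], int(d["sample_rate"]), d["untrained"])


@dataclass
class FilterBank2D:
    """Per output channel, a (N_TAPS x n_input_channels) decoding kernel."""

    kernels: np.ndarray  # (n_out, N_TAPS, n_in)
    cfs: np.ndarray
    sample_rate: int
    _fft_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kernels.shape[1] != N_TAPS:
            raise ValueError(f"filters must have exactly {N_TAPS} taps")

    @classmethod
    def from_1d(cls, bank: FilterBank1D) -> "FilterBank2D":
        """Diagonal initialization: column omega = f holds the 1-D filter."""
        n = len(bank.taps)
        kernels = np.zeros((n, N_TAPS, n))
        for f in range(n):
            kernels[f, :, f] = bank.taps[f]
        return cls(kernels, bank.cfs.copy(), bank.sample_rate)

    def save_npz(self, path) -> None:
        np.savez(path, kernels=self.kernels, cfs=self.cfs, sample_rate=self.sample_rate)

    @classmethod
    def load_npz(cls, path) -> "FilterBank2D":
        d = np.load(path)
        return cls(d["kernels"], d["cfs"], int(d["sample_rate"]))

    def _ffts(self, nfft: int) -> np.ndarray:
        """Cached block rFFTs of all kernels, shape (n_out, n_in, nfft//2+1).

        Only the fixed overlap-save block size is ever cached, keeping the
        footprint below ~100 MB for a 36-channel bank.
        """
        if nfft not in self._fft_cache:
            self._fft_cache.clear()
            self._fft_cache[nfft] = rfft(
                np.transpose(self.kernels, (0, 2, 1)), nfft, axis=-1
            )
        return self._fft_cache[nfft]


@dataclass
class EnvelopeMatrix:
    """Decoded (non-negative) envelopes plus their alignment offset."""

    envelopes: np.ndarray  # (n_channels, n_out_samples)
    sample_rate: int
    offset: int = DECODE_OFFSET  # envelope sample k <-> stimulus sample k+offset


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def binarize(raster: SpikeRaster, dt: float) -> np.ndarray:
    """Spike-count matrix x(t, omega): one row per channel, bins of ``dt`` s.

    Expects a cortical-output raster (a single azimuth row).
    """
    n_rows, n_ch = raster.shape
    if n_rows != 1:
        raise ValueError("binarize expects a 1 x n_channels cortical raster")
    n_bins = int(round(raster.duration / dt))
    out = np.zeros((n_ch, n_bins))
    for c in range(n_ch):
        t = raster.trains[0][c].spike_times
        idx = np.minimum((t / dt).astype(int), n_bins - 1)
        np.add.at(out[c], idx, 1.0)
    return out


def train_filter_1d(
    stim_envelopes: np.ndarray,
    spike_matrix: np.ndarray,
    sample_rate: int,
    cfs: np.ndarray | None = None,
    eps_rel: float = 1e-3,
    nperseg: int = 4096,
) -> FilterBank1D:
    """Analytic per-channel filters H = S_sx / (S_xx + eps).

    ``eps`` regularizes near-empty spectral bins of the Poisson response:
    eps = eps_rel * max(S_xx) per channel.  Channels with no spikes are
    flagged untrained and get a zero filter.
    """
    s = np.asarray(stim_envelopes, dtype=np.float64)
    x = np.asarray(spike_matrix, dtype=np.float64)
    if s.shape != x.shape:
        raise ValueError("stimulus envelopes and spike matrix must share shape")
    n_ch, n_t = s.shape
    if n_t < nperseg:
        raise ValueError("training signal shorter than the Welch segment")
    taps = np.zeros((n_ch, N_TAPS))
    untrained = np.zeros(n_ch, dtype=bool)
    for c in range(n_ch):
        if not np.any(x[c]):
            untrained[c] = True
            continue
        _, pxx = welch(x[c], fs=sample_rate, nperseg=nperseg)
        _, pxs = csd(x[c], s[c], fs=sample_rate, nperseg=nperseg)
        h_freq = pxs / (pxx + eps_rel * np.max(pxx))
        h_time = irfft(h_freq, nperseg)  # lag-domain kernel, circular
        lags = np.arange(N_TAPS) - CENTER
        taps[c] = h_time[lags % nperseg]
    if cfs is None:
        cfs = np.arange(n_ch, dtype=float)
    return FilterBank1D(taps, np.asarray(cfs, dtype=float), sample_rate, untrained)


_OS_BLOCK = 8192  # overlap-save block length for 2-D decoding


def _decode_fft(x: np.ndarray, filters: FilterBank2D) -> np.ndarray:
    """Valid-mode 2-D convolution via overlap-save block processing."""
    n_ch, n_t = x.shape
    if n_t < N_TAPS:
        raise ValueError("signal shorter than the filter")
    hf = filters._ffts(_OS_BLOCK)  # (n_out, n_in, bins)
    n_out = filters.kernels.shape[0]
    n_valid = n_t - N_TAPS + 1
    hop = _OS_BLOCK - (N_TAPS - 1)
    out = np.empty((n_out, n_valid))
    pos = 0
    while pos < n_valid:
        seg = x[:, pos : pos + _OS_BLOCK]
        if seg.shape[1] < _OS_BLOCK:
            seg = np.pad(seg, ((0, 0), (0, _OS_BLOCK - seg.shape[1])))
        xf = rfft(seg, axis=-1)
        z = irfft(np.einsum("oib,ib->ob", hf, xf), _OS_BLOCK, axis=-1)
        # circular-convolution samples >= N_TAPS-1 equal the linear result
        n_take = min(hop, n_valid - pos)
        out[:, pos : pos + n_take] = z[:, N_TAPS - 1 : N_TAPS - 1 + n_take]
        pos += hop
    return out


def decode(
    spike_matrix: np.ndarray, filters: FilterBank1D | FilterBank2D
) -> EnvelopeMatrix:
    """Decode envelopes from a spike-count matrix (negatives clipped to 0)."""
    x = np.asarray(spike_matrix, dtype=np.float64)
    if isinstance(filters, FilterBank1D):
        n_ch, n_t = x.shape
        if n_t < N_TAPS:
            raise ValueError("signal shorter than the filter")
        nfft = next_fast_len(n_t + N_TAPS - 1)
        xf = rfft(x, nfft, axis=-1)
        hf = rfft(filters.taps, nfft, axis=-1)
        z = irfft(xf * hf, nfft, axis=-1)[:, N_TAPS - 1 : n_t]
        sr = filters.sample_rate
    else:
        z = _decode_fft(x, filters)
        sr = filters.sample_rate
    return EnvelopeMatrix(np.clip(z, 0.0, None), sr)


def _mse(
    filters: FilterBank2D, x: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Envelope MSE of the raw (unclipped) decode, and the residual."""
    z = _decode_fft(x, filters)
    r = z - target
    return float(np.mean(r**2)), r


def train_filter_2d(
    init: FilterBank1D | FilterBank2D,
    stim_envelopes: np.ndarray,
    spike_matrix: np.ndarray,
    lr: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
    channels: np.ndarray | None = None,
) -> tuple[FilterBank2D, list]:
    """Gradient descent on envelope MSE, per output channel.

    Starts from the diagonal embedding of the 1-D filters; backtracking
    halves the step on overshoot, so the recorded loss trace is
    non-increasing.  ``channels`` optionally restricts training to a subset
    of output channels (others keep their initialization).

    Returns the trained bank and one loss trace per trained channel.
    """
    bank = FilterBank2D.from_1d(init) if isinstance(init, FilterBank1D) else init
    x = np.asarray(spike_matrix, dtype=np.float64)
    s = np.asarray(stim_envelopes, dtype=np.float64)
    n_ch, n_t = x.shape
    n_valid = n_t - N_TAPS + 1
    if n_valid < 1:
        raise ValueError("training signal shorter than the filter")
    target = s[:, DECODE_OFFSET : DECODE_OFFSET + n_valid]

    nfft = next_fast_len(n_t + N_TAPS - 1)
    xf = rfft(x, nfft, axis=-1)  # (n_in, bins), shared across channels
    kernels = bank.kernels.copy()
    traces = []
    train_set = range(n_ch) if channels is None else list(channels)

    for f in train_set:
        hf = rfft(kernels[f].T, nfft, axis=-1)  # (n_in, bins)
        step = lr
        z = irfft(np.sum(hf * xf, axis=0), nfft)[N_TAPS - 1 : n_t]
        r = z - target[f]
        loss = float(np.mean(r**2))
        trace = [loss]
        for _ in range(max_iter):
            # grad[n, w] = (2/Nv) * sum_k r[k] x_w[k + (N_TAPS-1) - n]
            rf = rfft(r, nfft)
            corr = irfft(xf * np.conj(rf), nfft, axis=-1)[:, :N_TAPS]
            grad = (2.0 / n_valid) * corr[:, ::-1].T  # (N_TAPS, n_in)
            gnorm2 = float(np.sum(grad**2))
            if gnorm2 == 0.0:
                break
            if step is None:
                step = loss / gnorm2  # Cauchy-like initial step
            improved = False
            for _bt in range(30):
                cand = kernels[f] - step * grad
                hf_c = rfft(cand.T, nfft, axis=-1)
                z_c = irfft(np.sum(hf_c * xf, axis=0), nfft)[N_TAPS - 1 : n_t]
                if not np.all(np.isfinite(z_c)):
                    raise FloatingPointError("non-finite loss during 2-D training")
                r_c = z_c - target[f]
                loss_c = float(np.mean(r_c**2))
                if loss_c <= loss:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            kernels[f] = cand
            rel = (loss - loss_c) / max(loss, 1e-30)
            loss, r = loss_c, r_c
            trace.append(loss)
            step *= 1.5  # cautious growth after a successful step
            if rel < tol:
                break
        traces.append(trace)
    return FilterBank2D(kernels, bank.cfs.copy(), bank.sample_rate), traces


def synthesize(env: EnvelopeMatrix, cfs: np.ndarray) -> AudioSignal:
    """Tone-carrier resynthesis: s(t) = sum_f A_f(t) sin(2 pi CF_f t).

    The output is peak-normalized to 0.9 (silence stays silent).
    """
    cfs = np.asarray(cfs, dtype=float)
    a = env.envelopes
    if len(cfs) != a.shape[0]:
        raise ValueError("envelope channels do not match center frequencies")
    n = a.shape[1]
    t = (np.arange(n) + env.offset) / env.sample_rate
    wave = np.einsum("ct,ct->t", a, np.sin(2 * np.pi * cfs[:, None] * t[None, :]))
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= 0.9 / peak
    return AudioSignal(wave, env.sample_rate)
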
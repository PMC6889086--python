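"""Stimulus reconstruction: optimal filters, decoding, synthesis."""

import numpy as np
import pytest

from cocktail import reconstruction as rc
from cocktail.midbrain import SpikeRaster, SpikeTrain

FS = 40_000


def _encoder_spikes(env, gain, seed):
    """Poisson spikes whose rate follows the envelope (simulated encoder)."""
    rng = np.random.default_rng(seed)
    rates = gain * env / env.max()
    return (rng.random(env.shape) < rates / FS).astype(float)


def _aligned(env, n_valid):
    return env[:, rc.DECODE_OFFSET : rc.DECODE_OFFSET + n_valid]


class TestBinarize:
    def _raster(self, times_per_ch, duration):
        trains = [[SpikeTrain(np.asarray(t), duration) for t in times_per_ch]]
        return SpikeRaster(trains, duration)

    def test_empty_is_zero(self):
        x = rc.binarize(self._raster([[], []], 0.1), 1 / FS)
        assert x.shape == (2, 4000) and not x.any()

    def test_single_spike_single_bin(self):
        x = rc.binarize(self._raster([[0.05], []], 0.1), 1 / FS)
        assert x.sum() == 1 and x[0, 2000] == 1

    def test_counts_preserved(self):
        times = [list(np.linspace(0.001, 0.099, 17)), [0.01, 0.02]]
        x = rc.binarize(self._raster(times, 0.1), 1 / FS)
        assert x.sum() == 19


class TestTrainFilter1D:
    def test_encoder_roundtrip_correlation(self):
        # spikes driven by the envelope itself decode back to it (r > 0.6)
        rng = np.random.default_rng(42)
        from conftest import _slow_envelopes

        # rate high enough that Poisson noise does not mask the filter's fit
        env = _slow_envelopes(rng, 2, 20 * FS, FS)
        spikes = _encoder_spikes(env, 1500.0, seed=1)
        bank = rc.train_filter_1d(env, spikes, FS)
        dec = rc.decode(spikes, bank)
        tgt = _aligned(env, dec.envelopes.shape[1])
        for c in range(2):
            r = np.corrcoef(dec.envelopes[c], tgt[c])[0, 1]
            assert r > 0.6

    def test_unrelated_spikes_give_no_filter(self):
        rng = np.random.default_rng(3)
        from conftest import _slow_envelopes

        env = _slow_envelopes(rng, 1, 10 * FS, FS)
        spikes = (rng.random(env.shape) < 100.0 / FS).astype(float)  # independent
        bank = rc.train_filter_1d(env, spikes, FS)
        dec = rc.decode(spikes, bank)
        tgt = _aligned(env, dec.envelopes.shape[1])
        r = np.corrcoef(dec.envelopes[0], tgt[0])[0, 1]
        assert abs(r) < 0.1

    def test_linearity_in_stimulus(self):
        rng = np.random.default_rng(4)
        from conftest import _slow_envelopes

        env = _slow_envelopes(rng, 1, 8 * FS, FS)
        spikes = _encoder_spikes(env, 120.0, seed=2)
        bank1 = rc.train_filter_1d(env, spikes, FS)
        bank2 = rc.train_filter_1d(2.0 * env, spikes, FS)
        assert np.allclose(bank2.taps, 2.0 * bank1.taps, rtol=1e-6, atol=1e-12)

    def test_empty_channel_flagged(self):
        env = np.abs(np.random.default_rng(5).normal(0, 1, (2, 5 * FS)))
        spikes = np.zeros_like(env)
        spikes[0, :: FS // 100] = 1.0
        bank = rc.train_filter_1d(env, spikes, FS)
        assert not bank.untrained[0] and bank.untrained[1]
        assert not bank.taps[1].any()

    def test_tap_count_enforced(self):
        with pytest.raises(ValueError):
            rc.FilterBank1D(np.zeros((2, 100)), np.arange(2.0), FS)


class TestTrainFilter2D:
    def test_zero_iterations_is_initialization(self, leakage_data):
        env, spikes, fs = leakage_data
        bank = rc.train_filter_1d(env, spikes, fs)
        bank2d, traces = rc.train_filter_2d(bank, env, spikes, max_iter=0)
        init = rc.FilterBank2D.from_1d(bank)
        assert np.array_equal(bank2d.kernels, init.kernels)

    def test_loss_non_increasing(self, leakage_data):
        env, spikes, fs = leakage_data
        bank = rc.train_filter_1d(env, spikes, fs)
        _, traces = rc.train_filter_2d(bank, env, spikes, max_iter=5, channels=[2])
        trace = traces[0]
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_gradient_matches_finite_differences(self):
        # tiny problem: compare the analytic gradient step against brute force
        rng = np.random.default_rng(11)
        n_ch, n_t = 2, rc.N_TAPS + 500
        env = np.abs(rng.normal(0, 1, (n_ch, n_t)))
        spikes = (rng.random((n_ch, n_t)) < 0.005).astype(float)
        bank = rc.FilterBank1D(
            rng.normal(0, 1e-3, (n_ch, rc.N_TAPS)), np.arange(2.0), FS
        )

        def loss_of(kernels, f):
            n_valid = n_t - rc.N_TAPS + 1
            target = env[:, rc.DECODE_OFFSET : rc.DECODE_OFFSET + n_valid]
            z = np.zeros(n_valid)
            for w in range(n_ch):
                z += np.convolve(spikes[w], kernels[f][:, w], mode="valid")
            return np.mean((z - target[f]) ** 2)

        init = rc.FilterBank2D.from_1d(bank)
        trained, traces = rc.train_filter_2d(init, env, spikes, max_iter=1, channels=[0])
        # the analytic step must not increase the brute-force loss
        assert loss_of(trained.kernels, 0) <= loss_of(init.kernels, 0) + 1e-18
        # and the recorded initial loss must match brute force exactly
        assert traces[0][0] == pytest.approx(loss_of(init.kernels, 0), rel=1e-9)

    def test_2d_beats_1d_under_leakage(self, leakage_data):
        env, spikes, fs = leakage_data
        bank = rc.train_filter_1d(env, spikes, fs)
        dec1 = rc.decode(spikes, bank)
        n_valid = dec1.envelopes.shape[1]
        tgt = _aligned(env, n_valid)
        mse1 = np.mean((dec1.envelopes - tgt) ** 2)
        bank2d, _ = rc.train_filter_2d(bank, env, spikes, max_iter=40)
        dec2 = rc.decode(spikes, bank2d)
        mse2 = np.mean((dec2.envelopes - tgt) ** 2)
        assert mse2 < 0.95 * mse1  # at least 5 % better


class TestDecode:
    def test_zero_spikes_zero_envelopes(self):
        bank = rc.FilterBank1D(
            np.random.default_rng(0).normal(0, 1, (3, rc.N_TAPS)), np.arange(3.0), FS
        )
        dec = rc.decode(np.zeros((3, 5000)), bank)
        assert not dec.envelopes.any()

    def test_valid_length_arithmetic(self):
        bank = rc.FilterBank1D(np.zeros((1, rc.N_TAPS)), np.arange(1.0), FS)
        dec = rc.decode(np.zeros((1, 4096)), bank)
        assert dec.envelopes.shape[1] == 4096 - 2048 + 1 == 2049

    def test_diagonal_2d_equals_1d(self):
        rng = np.random.default_rng(1)
        taps = rng.normal(0, 1, (3, rc.N_TAPS))
        bank = rc.FilterBank1D(taps, np.arange(3.0), FS)
        spikes = (rng.random((3, 6000)) < 0.01).astype(float)
        d1 = rc.decode(spikes, bank)
        d2 = rc.decode(spikes, rc.FilterBank2D.from_1d(bank))
        assert np.allclose(d1.envelopes, d2.envelopes, atol=1e-10)

    def test_too_short_rejected(self):
        bank = rc.FilterBank1D(np.zeros((1, rc.N_TAPS)), np.arange(1.0), FS)
        with pytest.raises(ValueError):
            rc.decode(np.zeros((1, 100)), bank)


class TestSynthesize:
    def test_single_channel_pure_tone(self):
        cfs = np.array([1000.0, 2000.0])
        env = np.zeros((2, 8000))
        env[0] = 1.0
        out = rc.synthesize(rc.EnvelopeMatrix(env, FS), cfs)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / FS)
        assert abs(freqs[np.argmax(spec)] - 1000.0) < 10.0
        assert np.max(np.abs(out.samples)) == pytest.approx(0.9)

    def test_silence(self):
        out = rc.synthesize(rc.EnvelopeMatrix(np.zeros((2, 4000)), FS), np.array([500.0, 900.0]))
        assert not out.samples.any()

    def test_two_channels_two_peaks(self):
        cfs = np.array([800.0, 3000.0])
        env = np.ones((2, 16000))
        out = rc.synthesize(rc.EnvelopeMatrix(env, FS), cfs)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / FS)
        for cf in cfs:
            near = spec[np.abs(freqs - cf) < 20]
            far = spec[(np.abs(freqs - cf) > 100) & (np.abs(freqs - cfs[0]) > 100) & (np.abs(freqs - cfs[1]) > 100)]
            assert near.max() > 10 * far.max()


class TestSerialization:
    def test_1d_roundtrip(self, tmp_path):
        bank = rc.FilterBank1D(
            np.random.default_rng(0).normal(0, 1, (2, rc.N_TAPS)),
            np.array([500.0, 1000.0]),
            FS,
        )
        bank.save_npz(tmp_path / "f1.npz")
        back = rc.FilterBank1D.load_npz(tmp_path / "f1.npz")
        assert np.array_equal(back.taps, bank.taps)
        assert back.sample_rate == FS

    def test_2d_roundtrip(self, tmp_path):
        bank = rc.FilterBank2D(
            np.random.default_rng(0).normal(0, 1, (2, rc.N_TAPS, 2)),
            np.array([500.0, 1000.0]),
            FS,
        )
        bank.save_npz(tmp_path / "f2.npz")
        back = rc.FilterBank2D.load_npz(tmp_path / "f2.npz")
        assert np.array_equal(back.kernels, bank.kernels)
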
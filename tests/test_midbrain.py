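"""Midbrain cue extraction and azimuth-tuned spiking."""

import numpy as np
import pytest

import cocktail as ck
from cocktail import midbrain as mb
from cocktail.cochlea import FilterbankSpec, analyze_binaural, erb_center_frequencies
from cocktail.scene import HeadModel, generate_sentence, spatialize

FS = 40_000


def _band_noise(rng, n=40_000, lo=300, hi=1200):
    """Noise band suitable for fine-structure cross-correlation."""
    from scipy.signal import butter, sosfilt

    sos = butter(4, [lo, hi], btype="band", fs=FS, output="sos")
    return sosfilt(sos, rng.normal(0, 1.0, n))


class TestComputeItd:
    def test_right_delayed_gives_negative_itd(self):
        # delaying the right ear means the LEFT ear leads: negative ITD
        rng = np.random.default_rng(1)
        x = _band_noise(rng)
        d = int(round(400e-6 * FS))  # 16 samples
        xr = np.r_[np.zeros(d), x[:-d]]
        itd, valid = mb.compute_itd(x, xr, FS)
        assert np.median(itd[valid]) == pytest.approx(-400.0, abs=25.0)

    def test_identical_ears_give_zero(self):
        rng = np.random.default_rng(2)
        x = _band_noise(rng)
        itd, valid = mb.compute_itd(x, x, FS)
        assert np.all(np.abs(itd[valid]) <= 12.5)

    def test_silent_frames_flagged_invalid(self):
        x = np.zeros(FS)
        itd, valid = mb.compute_itd(x, x, FS)
        assert not valid.any()

    def test_frame_longer_than_signal(self):
        with pytest.raises(ValueError):
            mb.compute_itd(np.zeros(100), np.zeros(100), FS)

    @pytest.mark.parametrize("true_us", [0, 200, -200, 656])
    def test_imposed_delay_recovered(self, true_us):
        rng = np.random.default_rng(3)
        x = _band_noise(rng)
        d = int(round(abs(true_us) * 1e-6 * FS))
        delayed = np.r_[np.zeros(d), x[: len(x) - d]]
        if true_us >= 0:  # right leads: left ear is delayed
            xl, xr = delayed, x
        else:
            xl, xr = x, delayed
        itd, valid = mb.compute_itd(xl, xr, FS)
        grid_us = round(d / FS * 1e6) * np.sign(true_us)
        assert np.median(itd[valid]) == pytest.approx(grid_us, abs=25.0)


class TestComputeIld:
    def test_half_amplitude_right(self):
        rng = np.random.default_rng(4)
        env = np.abs(rng.normal(0, 0.05, FS)) + 0.01
        ild, valid = mb.compute_ild(env, 0.5 * env, FS)
        assert np.allclose(ild[valid], 20 * np.log10(2.0), atol=0.01)

    def test_identical_is_zero(self):
        env = np.abs(np.random.default_rng(5).normal(0, 0.05, FS)) + 0.01
        ild, valid = mb.compute_ild(env, env, FS)
        assert np.allclose(ild[valid], 0.0, atol=1e-9)

    def test_silent_ear_flagged(self):
        env = np.abs(np.random.default_rng(6).normal(0, 0.05, FS)) + 0.01
        ild, valid = mb.compute_ild(env, np.zeros_like(env), FS)
        assert not valid.any()

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError):
            mb.compute_ild(-np.ones(FS), np.ones(FS), FS)


def _tuning():
    cfs = erb_center_frequencies(FilterbankSpec())
    return mb.SpatialTuningTable.for_head(HeadModel(), cfs)


def _cues_at(tuning, az_idx, n_ch=36, n_frames=50):
    """Cue map pinned exactly at one neuron's preferred cues, full level."""
    itd = np.full((n_ch, n_frames), tuning.pref_itd_us[az_idx])
    ild = np.tile(tuning.pref_ild_db[az_idx][:, None], (1, n_frames))
    return mb.BinauralCueMap(
        itd_us=itd,
        ild_db=ild,
        level=np.full((n_ch, n_frames), 1.0),
        valid=np.ones((n_ch, n_frames), bool),
        frame_rate=100.0,
        cfs=np.zeros(n_ch),
        level_ref=1.0,
    )


class TestFiringProbability:
    def test_preferred_cues_win(self):
        t = _tuning()
        cues = _cues_at(t, 3)  # +45 degrees
        rates = [mb.firing_probability(cues, t, a).mean() for a in range(5)]
        assert np.argmax(rates) == 3
        assert rates[3] > 0.7 * t.rate_max

    def test_anti_preferred_low(self):
        t = _tuning()
        cues = _cues_at(t, 4)  # +90
        r_anti = mb.firing_probability(cues, t, 0)  # -90 neuron
        assert np.all(r_anti < 0.2 * t.rate_max)

    def test_multiplication_like(self):
        # removing the ITD term drops the rate below half its tuned value
        t = _tuning()
        cues = _cues_at(t, 2)
        tuned = mb.firing_probability(cues, t, 2).mean()
        cues.itd_us[:] = 10_000.0  # ITD Gaussian term -> 0, ILD still preferred
        itd_dead = mb.firing_probability(cues, t, 2).mean()
        assert itd_dead < 0.5 * tuned

    def test_invalid_frames_emit_spontaneous(self):
        t = _tuning()
        cues = _cues_at(t, 2)
        cues.valid[:] = False
        r = mb.firing_probability(cues, t, 2)
        assert np.allclose(r, t.spontaneous_rate)

    def test_unknown_azimuth_index(self):
        t = _tuning()
        with pytest.raises(ValueError):
            mb.firing_probability(_cues_at(t, 0), t, 7)


class TestPoissonSpikes:
    def test_zero_rate_empty(self):
        train = mb.poisson_spikes(np.zeros(1000), 1e-4, seed=0)
        assert len(train) == 0

    def test_count_statistics(self):
        rate = np.full(int(10.0 / 1e-4), 100.0)
        train = mb.poisson_spikes(rate, 1e-4, seed=1)
        assert 1000 - 4 * np.sqrt(1000) <= len(train) <= 1000 + 4 * np.sqrt(1000)

    def test_seed_reproducible(self):
        rate = np.full(20_000, 80.0)
        a = mb.poisson_spikes(rate, 1e-4, seed=9)
        b = mb.poisson_spikes(rate, 1e-4, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_rate_consistency(self):
        rate = np.full(int(10.0 / 1e-4), 100.0)
        train = mb.poisson_spikes(rate, 1e-4, seed=2)
        assert abs(len(train) / 10.0 - 100.0) / 100.0 < 0.10

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            mb.poisson_spikes(np.ones(10), 0.0, seed=0)

    def test_rate_dt_guard(self):
        with pytest.raises(ValueError):
            mb.poisson_spikes(np.full(10, 5000.0), 1e-3, seed=0)


class TestLocalize:
    def test_single_source_row_wins(self):
        s = generate_sentence(55, 1.0, 140.0)
        b = spatialize(s, 45.0)
        cl, cr = analyze_binaural(b)
        raster = ck.localize(cl, cr, seed=0)
        totals = raster.counts().sum(axis=1)
        assert np.argmax(totals) == 3  # +45 row

    def test_azimuth_identification_rate(self):
        # argmax over rows recovers the source azimuth in >= 90 % of trials
        hits = 0
        trials = 0
        for az_idx, az in enumerate([-90, -45, 0, 45, 90]):
            for rep in range(4):
                s = generate_sentence(100 * az_idx + rep, 1.0, 120.0 + 10 * rep)
                b = spatialize(s, az)
                cl, cr = analyze_binaural(b)
                raster = ck.localize(cl, cr, seed=rep)
                hits += np.argmax(raster.counts().sum(axis=1)) == az_idx
                trials += 1
        assert hits / trials >= 0.90

    def test_silence_spontaneous_only(self):
        quiet = ck.AudioSignal(np.zeros(FS))
        b = ck.BinauralSignal(quiet, quiet)
        cl, cr = analyze_binaural(b)
        raster = ck.localize(cl, cr, seed=0)
        # 5 az x 36 ch x 1 s at the 1 Hz spontaneous rate -> expect ~180
        assert raster.counts().sum() < 180 + 4 * np.sqrt(180)

    def test_seed_reproducible(self, sentence):
        b = spatialize(sentence, 30.0)
        cl, cr = analyze_binaural(b)
        a = ck.localize(cl, cr, seed=3)
        c = ck.localize(cl, cr, seed=3)
        assert a.counts().tolist() == c.counts().tolist()


class TestSpikeContainers:
    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            mb.SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            mb.SpikeTrain(np.array([0.5, 1.5]), 1.0)

    def test_raster_roundtrip(self, tmp_path):
        trains = [
            [mb.SpikeTrain(np.array([0.1 * (c + 1)]), 1.0) for c in range(3)]
            for _ in range(5)
        ]
        raster = mb.SpikeRaster(trains, 1.0)
        path = tmp_path / "raster.npz"
        raster.save_npz(path)
        back = mb.SpikeRaster.load_npz(path)
        assert back.shape == raster.shape
        assert back.counts().tolist() == raster.counts().tolist()
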
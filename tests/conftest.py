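"""Shared fixtures.

The trained pipeline is expensive (cochlea + midbrain + cortex over several
seconds of audio), so it is built once per session and shared by the
integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import cocktail as ck
from cocktail import pipeline as pl


TRAIN_SEED = 123
TRAIN_DURATION = 6.0


@pytest.fixture(scope="session")
def pipe() -> pl.Pipeline:
    """Pipeline with 1-D reconstruction filters trained on clean speech."""
    p = pl.Pipeline()
    p.train(
        seed=TRAIN_SEED,
        duration=TRAIN_DURATION,
        use_2d=True,
        iters_2d=4,
        store_training=True,
    )
    return p


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def sentence() -> ck.AudioSignal:
    return ck.generate_sentence(101, duration=1.5, f0=130.0)


def _slow_envelopes(rng, n_ch, n_t, fs):
    """Non-negative, slowly varying band envelopes (speech-like timescale)."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(2, 8.0, fs=fs, output="sos")
    env = sosfiltfilt(sos, rng.normal(0, 1.0, (n_ch, n_t)), axis=1)
    env = np.clip(env, 0.0, None)
    return env / env.max()


@pytest.fixture(scope="session")
def leakage_data():
    """Simulated encoder whose spikes mix neighboring channel envelopes.

    Emulates gammatone spectral overlap: channel omega's firing rate encodes
    a weighted sum of nearby channels' envelopes, so a per-channel (1-D)
    decoder is structurally unable to undo the mixing while a 2-D decoder
    can.  Returns (envelopes, spike matrix, sample rate).
    """
    fs = 40_000
    n_ch, dur = 6, 8.0
    n_t = int(dur * fs)
    gen = np.random.default_rng(77)
    env = _slow_envelopes(gen, n_ch, n_t, fs)
    idx = np.arange(n_ch)
    leak = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2 * 0.8**2))
    rates = 180.0 * (leak @ env) / (leak @ env).max()
    spikes = (gen.random(rates.shape) < rates / fs).astype(float)
    return env, spikes, fs
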
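"""End-to-end scenario runner.

Wires the stages together (scene -> cochlea -> midbrain -> cortex ->
reconstruction -> evaluation) and reproduces the study's simulation
scenarios on synthetic sentences: monitor mode (single roving target),
selective mode (frontal target, symmetric maskers), TMR robustness, the
network-reconfiguration demo, and the frequency-tuning (Q) sweep.

Scale defaults are desk-sized: 1.5 s sentences, 15 degree azimuth grids and
5 repeats; the full-size grids (5 degrees, 20 repeats) are reachable through
the config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import cochlea, cortex, evaluation, midbrain, reconstruction, scene
from .signals import AudioSignal, BinauralSignal

_PRESETS = {
    "none": lambda: cortex.InhibitionMatrix.none(),
    "frontal": lambda: cortex.InhibitionMatrix.beamformer(2),  # 0 degrees
    "side": lambda: cortex.InhibitionMatrix.beamformer(4),  # +90 degrees
}


def inhibition_preset(name: str) -> cortex.InhibitionMatrix:
    if name not in _PRESETS:
        raise ValueError(f"unknown inhibition preset '{name}'")
    return _PRESETS[name]()


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario."""

    mode: str = "monitor"  # monitor | selective | robustness | reconfig | q_sweep
    azimuth_grid: list = field(default_factory=lambda: [0, 15, 30, 45, 60, 75, 90])
    tmr_grid: list = field(default_factory=lambda: [-13, -9, -5, -2, 0, 5, 13])
    n_repeats: int = 5
    seed: int = 0
    attend_azimuth: float = 0.0
    inhibition: str = "frontal"
    q: float | list | None = None
    sentence_duration: float = 2.5
    train_duration: float = 6.0
    use_2d: bool = True
    iters_2d: int = 4

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScenarioResult:
    """Per-trial records plus aggregates and provenance metadata."""

    mode: str
    records: list  # dicts: {grid point, repeat, EvaluationRecord fields...}
    aggregates: dict
    seed: int
    config_hash: str

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "aggregates": self.aggregates,
            "records": self.records,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


class Pipeline:
    """A configured instance of the full algorithm with trained filters."""

    def __init__(
        self,
        head: scene.HeadModel | None = None,
        fb_spec: cochlea.FilterbankSpec | None = None,
        q: float | None = None,
    ):
        self.head = head or scene.HeadModel()
        self.fb_spec = fb_spec or cochlea.FilterbankSpec()
        self.cfs = cochlea.erb_center_frequencies(self.fb_spec)
        self.tuning = midbrain.SpatialTuningTable.for_head(self.head, self.cfs)
        self.crossfreq = (
            None if q is None or np.isinf(q) else cortex.cross_freq_weights(q, self.cfs)
        )
        self.filters_1d: reconstruction.FilterBank1D | None = None
        self.filters_2d: reconstruction.FilterBank2D | None = None

    # -- core passes -------------------------------------------------------

    def cortex_config(self, inhibition: str) -> cortex.CorticalNetworkConfig:
        return cortex.CorticalNetworkConfig(
            inhibition=inhibition_preset(inhibition), crossfreq=self.crossfreq
        )

    def encode(
        self, binaural: BinauralSignal, inhibition: str, seed: int
    ) -> np.ndarray:
        """Front end through cortex; returns the spike-count matrix x(t, w)."""
        cl, cr = cochlea.analyze_binaural(binaural, self.fb_spec)
        raster = midbrain.localize(cl, cr, self.tuning, seed=seed)
        c_raster, _ = cortex.run_cortex(raster, self.cortex_config(inhibition))
        return reconstruction.binarize(c_raster, 1.0 / self.fb_spec.sample_rate)

    def train(
        self,
        seed: int = 1000,
        duration: float = 6.0,
        use_2d: bool = False,
        iters_2d: int = 4,
        inhibition: str = "frontal",
        store_training: bool = False,
    ) -> None:
        """Train decoding filters on a clean synthetic sentence at 0 degrees.

        Training sees only clean speech and its evoked spikes; mixtures never
        enter this phase.
        """
        rng = np.random.default_rng(seed)
        parts = [
            scene.generate_sentence(
                int(rng.integers(2**31)),
                duration=min(2.5, duration / 3),
                f0=float(rng.uniform(100, 180)),
                sample_rate=self.fb_spec.sample_rate,
            ).samples
            for _ in range(3)
        ]
        stim = AudioSignal(np.concatenate(parts), self.fb_spec.sample_rate)
        binaural = scene.spatialize(stim, 0.0, self.head)
        x = self.encode(binaural, inhibition, seed=int(rng.integers(2**31)))
        env = cochlea.analyze(stim, self.fb_spec).envelopes
        n_t = x.shape[1]
        target = np.zeros((env.shape[0], n_t))
        target[:, : env.shape[1]] = env[:, :n_t]
        self.filters_1d = reconstruction.train_filter_1d(
            target, x, self.fb_spec.sample_rate, cfs=self.cfs
        )
        if use_2d:
            self.filters_2d, _ = reconstruction.train_filter_2d(
                self.filters_1d, target, x, max_iter=iters_2d
            )
        if store_training:
            self.train_target, self.train_spikes = target, x

    def process(
        self, binaural: BinauralSignal, inhibition: str = "frontal", seed: int = 0
    ) -> AudioSignal:
        """Full pass: binaural mixture in, reconstructed waveform out."""
        if self.filters_1d is None:
            raise RuntimeError("pipeline filters not trained; call train() first")
        x = self.encode(binaural, inhibition, seed)
        filters = self.filters_2d if self.filters_2d is not None else self.filters_1d
        env = reconstruction.decode(x, filters)
        return reconstruction.synthesize(env, self.cfs)

    def reference(self, clean: AudioSignal, n_out: int) -> AudioSignal:
        """Clean-source reference aligned with a decoded output of n_out samples."""
        off = reconstruction.DECODE_OFFSET
        seg = clean.samples[off : off + n_out]
        out = np.zeros(n_out)
        out[: len(seg)] = seg
        return AudioSignal(out, clean.sample_rate)


def _sentences(rng: np.random.Generator, n: int, duration: float) -> list[AudioSignal]:
    """Draw n sentences from distinct talkers.

    Fundamental frequencies come from well-separated registers (like the
    different talkers of a recorded corpus) so concurrent sources are not
    gratuitously confusable by pitch.
    """
    registers = np.array([105.0, 145.0, 190.0])
    f0s = rng.permuted(registers)[:n] * rng.uniform(0.92, 1.08, size=min(n, 3))
    if n > 3:
        f0s = np.concatenate([f0s, rng.uniform(90, 200, n - 3)])
    return [
        scene.generate_sentence(
            int(rng.integers(2**31)), duration=duration, f0=float(f0s[i])
        )
        for i in range(n)
    ]


def _trial_records_aggregate(records: list, key: str) -> dict:
    import pandas as pd

    df = pd.DataFrame(records)
    agg = df.groupby(key).agg(
        stoi_mean=("stoi_vs_target", "mean"), stoi_sd=("stoi_vs_target", "std")
    )
    if "delta_stoi" in df and df["delta_stoi"].notna().any():
        agg = agg.join(
            df.groupby(key).agg(
                delta_mean=("delta_stoi", "mean"), delta_sd=("delta_stoi", "std")
            )
        )
    return {str(k): {c: float(v) for c, v in row.items()} for k, row in agg.iterrows()}


def make_pipeline(config: ScenarioConfig, q: float | None = None) -> Pipeline:
    pipe = Pipeline(q=q if q is not None else _scalar_q(config))
    pipe.train(
        seed=config.seed + 997,
        duration=config.train_duration,
        use_2d=config.use_2d,
        iters_2d=config.iters_2d,
    )
    return pipe


def _scalar_q(config: ScenarioConfig):
    return None if isinstance(config.q, list) else config.q


# -- scenario runners ------------------------------------------------------


def run_monitor(config: ScenarioConfig, pipe: Pipeline | None = None) -> ScenarioResult:
    """Single target roved across the azimuth grid; STOI vs azimuth."""
    pipe = pipe or make_pipeline(config)
    rng = np.random.default_rng(config.seed)
    # paired design: the same sentence set is roved across all azimuths
    targets = _sentences(rng, config.n_repeats, config.sentence_duration)
    records = []
    for az in config.azimuth_grid:
        for rep in range(config.n_repeats):
            target = targets[rep]
            binaural = scene.spatialize(target, az, pipe.head)
            out = pipe.process(binaural, "frontal", seed=int(rng.integers(2**31)))
            ref = pipe.reference(target, len(out.samples))
            s = evaluation.compute_stoi(ref, out)
            records.append(
                {
                    "azimuth": az,
                    "repeat": rep,
                    "stoi_vs_target": s,
                    "predicted_intelligibility_pct": evaluation.predicted_intelligibility(
                        float(np.clip(s, 0, 1))
                    ),
                }
            )
    agg = _trial_records_aggregate(records, "azimuth")
    means = [v["stoi_mean"] for v in agg.values()]
    cv = float(np.std(means) / np.mean(means))
    return ScenarioResult(
        "monitor",
        records,
        {"per_azimuth": agg, "stoi_cv_across_azimuths": cv},
        config.seed,
        config.config_hash(),
    )


def _selective_trial(
    pipe: Pipeline,
    rng: np.random.Generator,
    separation: float,
    tmr_db: float,
    duration: float,
    swap: bool,
) -> evaluation.EvaluationRecord:
    target, m1, m2 = _sentences(rng, 3, duration)
    if swap:
        m1, m2 = m2, m1
    spec = scene.SceneSpec(
        target=(target, 0.0),
        maskers=[(m1, +separation), (m2, -separation)] if separation > 0 else [
            (m1, 0.0),
            (m2, 0.0),
        ],
        tmr_db=tmr_db,
    )
    binaural = scene.mix_scene(spec, pipe.head)
    out = pipe.process(binaural, "frontal", seed=int(rng.integers(2**31)))
    n_out = len(out.samples)
    return evaluation.delta_stoi(
        out,
        pipe.reference(target, n_out),
        [pipe.reference(m1, n_out), pipe.reference(m2, n_out)],
    )


def run_selective(config: ScenarioConfig, pipe: Pipeline | None = None) -> ScenarioResult:
    """Frontal target, symmetric maskers at each separation, 0 dB TMR.

    Each repeat is run twice with the two masker sentences' locations
    swapped, mirroring the study design.
    """
    pipe = pipe or make_pipeline(config)
    rng = np.random.default_rng(config.seed)
    records = []
    for sep in config.azimuth_grid:
        for rep in range(config.n_repeats):
            for swap in (False, True):
                rec = _selective_trial(
                    pipe, rng, sep, 0.0, config.sentence_duration, swap
                )
                records.append(
                    {"separation": sep, "repeat": rep, "swap": swap, **rec.to_dict()}
                )
    agg = _trial_records_aggregate(records, "separation")
    return ScenarioResult(
        "selective",
        records,
        {"per_separation": agg},
        config.seed,
        config.config_hash(),
    )


def run_robustness(config: ScenarioConfig, pipe: Pipeline | None = None) -> ScenarioResult:
    """Target at 0, maskers fixed at +-90; TMR varied over the grid."""
    pipe = pipe or make_pipeline(config)
    if not all(-13 <= t <= 13 for t in config.tmr_grid):
        raise ValueError("TMR grid must lie within [-13, 13] dB")
    rng = np.random.default_rng(config.seed)
    records = []
    for tmr in config.tmr_grid:
        for rep in range(config.n_repeats):
            rec = _selective_trial(
                pipe, rng, 90.0, tmr, config.sentence_duration, swap=False
            )
            records.append({"tmr_db": tmr, "repeat": rep, **rec.to_dict()})
    agg = _trial_records_aggregate(records, "tmr_db")
    # estimate where delta crosses zero
    tmrs = sorted(agg, key=float)
    deltas = [agg[t].get("delta_mean", np.nan) for t in tmrs]
    crossing = None
    for i in range(1, len(deltas)):
        if deltas[i - 1] < 0 <= deltas[i]:
            t0, t1 = float(tmrs[i - 1]), float(tmrs[i])
            d0, d1 = deltas[i - 1], deltas[i]
            crossing = t0 - d0 * (t1 - t0) / (d1 - d0)
            break
    return ScenarioResult(
        "robustness",
        records,
        {"per_tmr": agg, "delta_zero_crossing_db": crossing},
        config.seed,
        config.config_hash(),
    )


def run_reconfig(config: ScenarioConfig, pipe: Pipeline | None = None) -> ScenarioResult:
    """Two concurrent sentences (S1 at 0, S2 at +90) under three wirings."""
    pipe = pipe or make_pipeline(config)
    rng = np.random.default_rng(config.seed)
    s1, s2 = _sentences(rng, 2, config.sentence_duration)
    spec = scene.SceneSpec(target=(s1, 0.0), maskers=[(s2, 90.0)], tmr_db=0.0)
    binaural = scene.mix_scene(spec, pipe.head)
    n = max(len(s1.samples), len(s2.samples))
    mixture = AudioSignal(
        s1.padded_to(n).samples + s2.padded_to(n).samples, s1.sample_rate
    )
    records = []
    for preset in ("none", "frontal", "side"):
        out = pipe.process(binaural, preset, seed=int(rng.integers(2**31)))
        n_out = len(out.samples)
        records.append(
            {
                "preset": preset,
                "stoi_vs_s1": evaluation.compute_stoi(pipe.reference(s1, n_out), out),
                "stoi_vs_s2": evaluation.compute_stoi(pipe.reference(s2, n_out), out),
                "stoi_vs_mixture": evaluation.compute_stoi(
                    pipe.reference(mixture, n_out), out
                ),
            }
        )
    return ScenarioResult(
        "reconfig",
        records,
        {r["preset"]: {k: v for k, v in r.items() if k != "preset"} for r in records},
        config.seed,
        config.config_hash(),
    )


def run_q_sweep(config: ScenarioConfig) -> ScenarioResult:
    """Single target at 0 degrees for each Q; filters retrained per finite Q."""
    qs = config.q if isinstance(config.q, list) else [0.85, 2.5, 5.1, 23.4]
    records = []
    for q in qs:
        pipe = Pipeline(q=None if q is None or np.isinf(q) else q)
        pipe.train(
            seed=config.seed + 997,
            duration=config.train_duration,
            use_2d=config.use_2d,
            iters_2d=config.iters_2d,
        )
        rng = np.random.default_rng(config.seed)
        for rep in range(config.n_repeats):
            (target,) = _sentences(rng, 1, config.sentence_duration)
            binaural = scene.spatialize(target, 0.0, pipe.head)
            out = pipe.process(binaural, "frontal", seed=int(rng.integers(2**31)))
            ref = pipe.reference(target, len(out.samples))
            s = evaluation.compute_stoi(ref, out)
            records.append(
                {"q": float(q) if q is not None else np.inf, "repeat": rep, "stoi_vs_target": s}
            )
    agg = _trial_records_aggregate(records, "q")
    return ScenarioResult(
        "q_sweep", records, {"per_q": agg}, config.seed, config.config_hash()
    )


RUNNERS = {
    "monitor": run_monitor,
    "selective": run_selective,
    "robustness": run_robustness,
    "reconfig": run_reconfig,
    "q_sweep": run_q_sweep,
}


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    if config.mode not in RUNNERS:
        raise ValueError(f"unknown mode '{config.mode}'")
    return RUNNERS[config.mode](config)
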
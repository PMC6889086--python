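"""Segregating a frontal target from two symmetric maskers.

The cortical network attends 0 degrees (frontal beamformer).  With maskers
at +-45 degrees and 0 dB target-to-masker ratio, the reconstruction
resembles the target far more than the maskers; delta STOI quantifies that.
"""

import cocktail as ck
from cocktail.pipeline import Pipeline

pipe = Pipeline()
pipe.train(seed=1120, duration=6.0)

target = ck.generate_sentence(seed=31, duration=1.5, f0=120.0)
m1 = ck.generate_sentence(seed=32, duration=1.5, f0=100.0)
m2 = ck.generate_sentence(seed=33, duration=1.5, f0=175.0)
scene = ck.mix_scene(
    ck.SceneSpec(target=(target, 0.0), maskers=[(m1, 45.0), (m2, -45.0)], tmr_db=0.0)
)
out = pipe.process(scene, inhibition="frontal", seed=9)

n = len(out.samples)
rec = ck.delta_stoi(
    out,
    pipe.reference(target, n),
    [pipe.reference(m1, n), pipe.reference(m2, n)],
)
print(f"STOI vs target : {rec.stoi_vs_target:.3f}")
print(f"STOI vs maskers: {[round(s, 3) for s in rec.stoi_vs_maskers]}")
print(f"delta STOI     : {rec.delta_stoi:+.3f}")
# positive delta = the output is closer to the attended target than to
# either masker; at 45 deg separation the benefit is well developed
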
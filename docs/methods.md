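# Methods

`cocktail` implements a physiologically inspired algorithm for binaural
sound-source segregation. Binaural audio is transformed into spike trains by
a cochlear filterbank and a midbrain spatial-localization network, processed
by a cortical spiking network whose cross-spatial-channel inhibition selects
one spatial stream, and decoded back into audio by linear stimulus
reconstruction. This note describes each stage's model, the parameters that
matter, the synthetic stimuli, and the numerical and design choices that
were genuinely open.

## Cochlear stage

Each ear signal is filtered into 36 frequency channels by 4th-order
gammatone filters (Slaney-style IIR design via `scipy.signal.gammatone`)
with center frequencies equally spaced on the ERB-rate scale from 300 Hz to
5000 Hz inclusive. Channel envelopes are the magnitude of the analytic
signal, lowpassed at 400 Hz with a 4th-order zero-phase Butterworth filter
and clipped at zero — the standard vocoder notion of an envelope; the
physiological literature does not pin down a unique definition, and this one
matches the filterbank depiction the model is built around.

## Midbrain spatial-localization network

For every channel, interaural cues are measured in 20 ms frames with a
10 ms hop:

- **ITD**: the lag (±800 μs grid, one 40 kHz sample resolution) maximizing
  the normalized interaural cross-correlation, refined by parabolic
  interpolation to sub-sample precision. Channels with CF ≥ 1.2 kHz
  correlate mean-removed *envelopes* instead of fine structure, because the
  fine-structure correlation is phase-ambiguous once the period is shorter
  than the lag range. Sign convention: positive ITD = right ear leads =
  source to the right.
- **ILD**: `10·log10(E_L/E_R)` over the frame's envelope energy (equal to
  the amplitude level difference in dB). Frames with envelope RMS below
  1e-4 in either ear are flagged invalid.

Five model neurons per channel prefer −90°, −45°, 0°, +45°, +90°. Their
preferred ITD/ILD values are read from the head model at those azimuths (the
same model used for spatialization, so tuning matches the rendered cues, as
the original tuning was matched to measured HRTFs). Each neuron's drive is
the sum of two Gaussian tuning terms,

    drive = exp(−(ITD−ITD*)²/2σ_itd²) + exp(−(ILD−ILD*)²/2σ_ild²),

passed through a threshold sigmoid `rate_max / (1+exp(−slope·(drive−θ)))`.
Adding before a threshold nonlinearity approximates a multiplication of the
two cues: the rate with one matched cue is far less than half the rate with
both matched.

Defaults were fixed by a documented calibration, not per-experiment fitting:

| parameter | value | rationale |
|---|---|---|
| σ_itd | 150 μs | adjacent preferred azimuths are ~380 μs apart near the midline; this width keeps intermediate azimuths (15–30°) covered |
| σ_ild | 4 dB | same coverage argument on the ILD axis |
| θ, slope | 1.7, 3.4 | drive 2 → ≈0.77·rate_max, drive 1 → ≈0.09 (single-cue leak stays below the cortical interneuron threshold), drive 0 → ≈0.01 |
| rate_max | 300 Hz | the decode stage is Poisson-noise-limited; a higher peak rate (still physiological for midbrain localization neurons) buys reconstruction fidelity while rate·dt = 0.03 stays far below the Bernoulli bound |
| spontaneous rate | 1 Hz | invalid/silent frames; avoids degenerate all-empty training responses |

The rate on valid frames is additionally multiplied by a scene-normalized
linear gain, `clip(level / level_ref, 0, 1)`, where `level` is the frame's
binaural mean envelope RMS and `level_ref` is the 95th percentile of level
over all valid frames and channels of the current scene. This makes the
spike rate track the band envelope (the information the reconstruction
stage decodes) while silence stays near zero; it acts like a slow scene-wide
gain control. How firing probability scales with absolute stimulus energy
was an open choice; a saturating (compressive) gain was tried and rejected
because it crushes envelope modulation depth and with it reconstruction
quality.

Spikes are drawn per 0.1 ms bin as Bernoulli trials with p = rate·dt
(rate·dt < 0.2 enforced), frame-rate cues being upsampled by zero-order
hold.

## Cortical network

One identical network per frequency channel. Inputs from the five spatial
channels excite relay neurons (R, one per azimuth) and interneurons (I, one
per azimuth); interneurons inhibit relay neurons of *other* spatial channels
according to a 5×5 binary matrix; all five relay neurons excite one cortical
output neuron (C). All nodes are conductance-based leaky integrate-and-fire
neurons:

    C_m dV/dt = −g_L(V−E_rest) − g_E(t)(V−E_exc) − g_I(t)(V−E_inh)

with E_rest = reset = −60 mV, threshold −40 mV, E_exc = 0 mV, E_inh =
−70 mV, absolute refractory period 3 ms. Synaptic kernels are normalized to
unit peak so the quoted conductances are peak values: input→I an alpha
function (τ = 1 ms, 0.11 nS); input→R and R→C a difference of exponentials
(rise 1 ms, fall 3 ms, 0.07 nS); I→R a difference of exponentials with
rise 4 ms and fall 1000 ms at 0.2 nS, whose second-long tail produces the
sustained off-target suppression the selective mode depends on.

The source model gives synaptic conductances but neither the leak
conductance nor the membrane capacitance, so only conductance *ratios* are
dynamically meaningful. Both are exposed in the config; the defaults come
from a one-off calibration sweep: g_L = 0.03 nS, τ_m = 20 ms (C_m =
g_L·τ_m) puts a relay neuron at 75 Hz under a 100 Hz Poisson input through
its 0.07 nS synapse — inside the 30–80 Hz band the calibration targets —
while keeping the downstream C neuron responsive.

Integration is exponential Euler at dt = 0.1 ms. The membrane decay and
both synapse state updates are exact for piecewise-constant conductances;
a guard rejects dt larger than a tenth of the fastest synaptic time
constant. Reset potential equals the resting potential (unstated in the
source model). The simulation is fully deterministic.

### Inhibition presets

- `none` (monitor): the 5×5 matrix is zero.
- `frontal`: only the 0° interneuron inhibits the other four relay rows.
- `side`: only the +90° interneuron row is active.

The frontal wiring shows both behaviors of interest without reconfiguration:
a lone source anywhere is relayed (the 0° interneuron is barely driven), and
adding a frontal target to a spatially separated mixture recruits the
inhibition that suppresses the other rows.

### Cross-frequency tuning (Q)

Optional spread of input across neighboring channels with Gaussian weights
`w_ij = exp(−(CF_j−CF_i)²/2σ_i²)`, σ_i = CF_i/(2√(2 ln 2)·Q), i.e. Q is
CF over the tuning curve's full width at half maximum. (The standard FWHM
form is used; Q = 23.4 leaves adjacent-channel weights below 0.5, the
channels-essentially-independent regime.) Inside the network the weight rows
are normalized to unit sum before scaling the input→R conductances, so
broadening the tuning blurs information across channels *without changing
total excitatory drive*; unnormalized weights would inject up to 5× extra
drive at low Q, and the resulting extra spikes measurably improve
reconstructions at moderate Q for reasons that have nothing to do with
tuning width. With normalization Q acts as a pure spectral blur, and Q = ∞
reduces to the identity exactly (bit-identical to the independent-channel
pipeline). Interneurons receive no cross-frequency input.

## Stimulus reconstruction

Per channel, a linear filter maps the cortical spike train onto the clean
stimulus envelope of that channel. The 1-D filter is the frequency-domain
Wiener solution H = S_sx/(S_xx + ε) with Welch/CSD estimates (default
segment 4096 samples, 50 % overlap) and ε = 1e-3·max(S_xx) to regularize
the near-empty bins of a Poisson response spectrum. The kernel is 2048 taps
(51.2 ms at 40 kHz), *acausal* and centered on zero lag — spikes lag the
stimulus that caused them, and the constant front-end latency (about 4 ms of
spatialization and filterbank group delay) is absorbed by the acausal taps
during training.

The 2-D filter adds an input-channel dimension (2048 × 36 per output
channel), initialized with the 1-D filter on its own channel and zeros
elsewhere, and fine-tuned by batch gradient descent on the decoded-envelope
MSE (valid-mode 2-D convolution). Steps use a Cauchy initial step length,
backtracking halving on overshoot (loss trace is non-increasing by
construction), mild step growth after success, and stop at a relative
improvement below 1e-5 or the iteration cap. Gradients are computed in the
frequency domain with shared input FFTs; the analytic gradient is verified
against brute-force convolution in the tests.

Decoding is valid-mode convolution: a T-sample spike matrix yields
T − 2047 envelope samples aligned to stimulus samples starting at 1023
(`DECODE_OFFSET`); reference signals are trimmed from the start accordingly
before scoring. The 2-D decode runs as overlap-save block convolution
(8192-sample blocks) so the kernel-FFT cache stays under ~100 MB for a
36-channel bank. Negative decoded values are clipped to zero. Synthesis
multiplies each decoded envelope onto a zero-phase sine carrier at the
channel CF and sums channels without weighting, peak-normalizing to 0.9.

The scenario runner uses the 2-D filter by default (a small fixed budget of
4 descent iterations from the 1-D initialization): the model's presented
results rest on the 2-D filter, which measurably improves end-to-end
intelligibility over the 1-D one.

Filter training only ever sees clean speech at 0° and its evoked spikes;
mixtures never enter training. Filters are retrained when channels interact
(finite Q), and reused otherwise.

## Evaluation

STOI is implemented from its published definition: resample to 10 kHz,
remove frames more than 40 dB below the loudest reference frame (256-sample
Hann frames, 50 % overlap), 512-point STFT, 15 one-third-octave bands from
150 Hz, and for every band and 30-frame (384 ms) segment the correlation of
the reference band envelope with the processed envelope after per-segment
normalization and clipping at the −15 dB signal-to-distortion bound; scores
average over bands and segments. Two properties worth keeping in mind when
reading results: the measure is invariant to global gain of the processed
signal, and *unrelated* signals do not score zero — the clipping step gives
speech-versus-noise and speech-versus-other-speech floors around 0.15–0.45.
The segregation measure Δ (target-referenced minus masker-referenced STOI)
subtracts most of that floor out; Δ here uses the *mean* over the
masker-referenced scores (max available as an option), because the max over
two independent maskers is biased about −0.1 when target and maskers are
spatially indistinguishable, where symmetry demands Δ ≈ 0.

Predicted subjective intelligibility uses the printed logistic map
`100/(1+exp(−13.1903·STOI+6.5192))`. The 50 % TMR threshold is the lowest
TMR at which the target-referenced score wins at least half the trials,
linearly interpolated between grid points and flagged unbounded when the
win fraction never reaches one half.

## Synthetic stimuli and head model

The scene module replaces a licensed speech corpus and measured mannequin
HRTFs, so every experiment is reproducible from a seed with no downloads.

**Sentences** are amplitude-modulated harmonic complexes: a fundamental
(90–200 Hz across talkers; concurrent talkers in a scene draw from
well-separated registers near 105/145/190 Hz) with ±4 % slow drift; 2–4
formant-like Gaussian
spectral peaks whose centers glide within 300–5000 Hz; *each formant
carries its own* 4–8 Hz syllabic envelope (a single global envelope makes
all band envelopes co-modulated, which inflates the chance STOI similarity
between unrelated sentences); 1–3 word-gap pauses of 60–150 ms; 50 ms
onset/offset ramps; RMS normalized to 0.05. Default duration in the
scenario runner is 2.5 s, on the scale of the short command sentences the
generator emulates.

**Spatialization** uses the Woodworth spherical-head ITD,
`(a/c)(sin θ + θ)` with a = 8.75 cm and c = 343 m/s (656 μs at ±90°),
applied as a 64-tap Kaiser-windowed-sinc fractional delay of the far ear,
plus an ILD that grows linearly in |sin θ| and with log-frequency from 0 dB
at 300 Hz to 10 dB (at 90°) at 5 kHz, realized as 255-tap linear-phase FIRs
splitting the level difference symmetrically between ears with the
per-frequency two-ear mean power pinned to the input level. Measured HRTF
impulse-response pairs (`az{±NN}_L.wav` / `az{±NN}_R.wav`) can be dropped in
instead. What the parametric model does *not* emulate: pinna spectral cues,
room reverberation, elevation, and source distance; passing tests therefore
say nothing about robustness to reverberant or elevated sources.

**Mixtures**: the target-to-masker ratio (in dB) is enforced against each
masker individually on pre-spatialization mono energies; sources are then
spatialized and summed per ear with zero-padding to the longest.

## Scenario runner scale

The runner defaults to desk-scale settings chosen once: 2.5 s sentences,
15° azimuth grids, 5 repeats per grid point, a 6 s training stimulus
(three concatenated sentences), and a small fixed iteration budget (2–4)
when 2-D filters are fine-tuned inside scenarios. Full-scale settings (5°
grids, 20 repeats, longer training, more 2-D iterations) are plain config
values. Aggregates report per-grid-point means and per-trial standard
deviations, and every result file embeds the config hash and seed.

## Known limitations

- Reconstruction quality is spike-budget-limited: with ~50–150 Hz cortical
  rates per channel, decoded envelopes carry visible Poisson noise, and
  single-target STOI plateaus near 0.5–0.65 against a tone-vocoder ceiling
  of ~0.69 measured with ideal envelopes.
- Binaural cue extraction assumes at most one dominant source per
  channel-frame (glimpsing); heavily overlapped spectra degrade the 0°
  channel's purity and with it Δ.
- The five-azimuth spatial sampling leaves intermediate azimuths encoded by
  weaker, shared activity; widths were chosen so this costs little for a
  single source, but localization *readout* precision between preferred
  azimuths is inherently coarse.
- The additive-then-sigmoid cue combination leaks single-cue drive (ILD is
  uninformative below ~1 kHz), bounding masker suppression; the sigmoid
  operating point trades this leak against sensitivity at intermediate
  azimuths.
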
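# Methods

This package implements a complete micro-Doppler-radar gait-analysis chain:
a synthetic walking-human radar simulator, the continuous-wave (CW) baseband
signal model, time-velocity spectrograms, extraction of three velocity
envelopes, and classification of young vs. elderly gait with an LSTM
sequence classifier and a velocity-parameter SVM baseline under a repeated
hold-out protocol.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Radar signal model

A monostatic CW radar at carrier `f0 = 24 GHz` (wavelength λ = c/f0 ≈ 12.49
mm) illuminates a walker approaching along the boresight.  The demodulated
complex baseband echo of N point scatterers is

    s_R(t) = Σ_i η_i A exp(j φ_i(t)),      φ_i(t) = −4π R_i(t)/λ,

with per-scatterer reflectivity η_i ∈ (0, 1], transmit amplitude A, and
radial range R_i(t).  The phase is evaluated from the full range track, which
reduces to the constant-velocity form when R_i(t) = R_i − v t.  A scatterer
approaching at radial velocity v produces the Doppler shift f_d = 2v/λ
(160.11 Hz per m/s at 24 GHz).  Range attenuation is omitted: the η_i are
fixed amplitude ratios, not a propagation model.  Measurement noise is
circular complex white Gaussian with per-component standard deviation
`noise_sd`; the default 0.03 puts the simulated SNR near 25 dB.  The noise
model and level are choices of this package — the measurement campaign the
pipeline emulates does not characterize its noise.

Sampling at fs = 600 Hz bounds the unambiguous radial velocity at the
Nyquist velocity (fs/2)·λ/2 ≈ 1.874 m/s.  The simulator refuses parameter
sets that reach it; the synthesizer merely warns for hand-built
trajectories, since measured data may legitimately contain aliasing.

## Synthetic walker

The walker is five point scatterers: torso, two feet, two tibiae.

* **Torso**: constant mean speed plus a sinusoidal fluctuation at two
  oscillations per gait cycle (one per step).
* **Feet**: each cycle splits into a stance phase (fraction 0.45) and a
  swing phase.  During stance the foot's radial velocity is a slow half-sine
  bump bounded by the *stance residual velocity*; during swing it follows a
  raised-cosine-flanked pulse with a flat plateau (0.65 of the swing) at the
  *swing peak velocity*.  Left and right feet are exactly half a cycle out
  of phase.
* **Tibiae**: midway between torso and same-side foot, v = (v_torso +
  v_foot)/2.

Ranges are the integrals of these velocity tracks starting near 9 m (a 10 m
walkway), with small random per-scatterer offsets to decorrelate carrier
phases.  A swing peak of exactly zero is interpreted as "no stepping": all
five scatterers ride the torso track (the degenerate rigid-body case used in
tests).

Default class parameters (configurable; young/elderly): torso speed 1.3 ±
0.08 / 1.0 ± 0.15 m/s, torso fluctuation 0.15 / 0.19 m/s, cycle duration
1.05 ± 0.05 / 1.15 ± 0.08 s, swing peak 1.7 / 1.4 m/s, stance residual
0.06 / 0.12 m/s.  The direction of every contrast (slower torso, slower
swing, longer cycle, noisier stance) follows the gait-slowing literature;
the magnitudes are this package's choices, not measured effect sizes, and
the configuration file is the single source of truth for them.  Per-
participant draws use symmetric ±2 SD truncated normals (class means stay
unbiased; no draw can reach the Nyquist velocity).  The swing peak scales
with the participant's own torso-speed draw — faster walkers swing faster —
with the configured swing SD acting as residual jitter, capped at 0.98×
Nyquist.

Reflectivities default to torso 1.0, feet 0.24, tibiae 0.06.  These values
resolve a real tension.  The power-weighted mean envelope is pulled below
the torso speed by the slow limb scatterers in proportion to their power
fraction, so recovering the torso speed from the time-averaged mean envelope
to within 5 % requires light limbs; but the stance foot must stay above the
ρ = 0.2 relative amplitude threshold even in frames where the torso sits at
a velocity extremum and is maximally concentrated by the STFT (a
stationary-phase effect), which requires feet near η ≈ 0.22 or above.  Feet
at 0.24 with near-silent tibiae satisfy both; the slow stance bump and the
swing plateau keep the feet spectrally concentrated where detection matters.
The swing plateau and the swing/speed coupling also raise the feet's
cycle-mean velocity, which the 5 % mean-envelope budget needs.

**What the simulator does not emulate**: articulated biomechanics, arm
swing, torso/limb micro-motions beyond the tracks above, range-dependent
amplitudes, clutter, multipath, site-dependent background noise, and
realistic within-class correlation structure.  Classes are separable only
through the configured parameter distributions — with identical class
configurations the generator is an exact null (exchangeable classes), which
the tests use as a negative control.  Passing tests on this generator
demonstrates that the pipeline recovers what the generator encodes; it does
not demonstrate classification accuracy on real cohorts, and the synthetic
classes are more separable in simple summary statistics than a real cohort
would be (the SVM baseline can reach very high accuracy here).

## Spectrogram

Short-time Fourier transform with a symmetric 128-sample Hamming window
(0.54 − 0.46 cos(2πn/(L−1))), unnormalized forward DFT, frames fully
interior (no edge padding) and center-timestamped, squared magnitude kept as
power.  Velocity bins relabel DFT frequencies through v = f·λ/2 and span
(−fs/2, fs/2]·λ/2 in exactly 128 bins of ≈ 0.0293 m/s; approaching motion is
positive.  Per-frame Parseval holds exactly as Σ_bins |S|² = L · Σ_samples
|w·s|².  The hop is not dictated by the reference protocol; the default of 8
samples (75 frames/s) makes a two-cycle steady-state interval come out
around 150 frames, inside the 99–224-frame range that protocol reports.

**Analysis-interval selection.**  The two-cycle steady-state crop needs the
gait-cycle duration.  The per-frame *total* power turns out to carry almost
no periodicity in this signal model (by Parseval it equals the windowed
|s(t)|² energy, whose scatterer-interference beats have effectively random
phase), so the estimator instead autocorrelates the mean-removed spectrogram
frames along time, summed over velocity bins — a direct self-similarity of
the time-velocity pattern.  Walking gives near-unity peaks at every multiple
of the *step* period, because the two legs paint nearly identical
half-cycle patterns.  The estimator therefore takes the smallest significant
peak lag within [0.3, 1.8] s — the step period — and doubles it (a gait
cycle is two steps).  A peak is significant at correlation ≥ 0.5 and ≥ 0.8
of the highest peak; genuine gait sits near 0.99 while the smoothed
noise floor of aperiodic recordings (adjacent frames share samples through
the overlapping windows) stays below ≈ 0.35, so the guard cleanly rejects
recordings without gait periodicity.  The crop of round(2·period/frame_dt)
frames is centered in the recording.

## Envelopes

Per frame:

* mean envelope v_m = Σ v·P(v) / Σ P(v), over the **full** velocity axis
  including negative velocities; zero-power frames are flagged undefined;
* significant peaks: local maxima of amplitude |S| (a bin strictly greater
  than both neighbours; for plateaus the leftmost bin of a maximal run that
  exceeds both run-neighbours counts once; endpoints ineligible) whose
  amplitude exceeds ρ · max|S| of that frame, with ρ = 0.2;
* v_u / v_l: the largest / smallest significant-peak velocity.

Frames with no significant peak carry the previous frame's v_u/v_l forward
(logged); an empty first frame is an error.  This keeps classifier input
sequences gap-free; the alternative (dropping frames) would entangle
sequence length with SNR.  The relative threshold is what cancels
background components: anything whose amplitude stays below ρ times the
frame maximum can never become a peak, so v_u/v_l ignore it — the package
tests this with band-limited background noise injected into the empty
receding-velocity band.

The twelve **velocity parameters** for the SVM baseline are mean,
population standard deviation (divide by n), max and min of v_u, v_m, v_l
in that fixed order.  The earlier velocity-parameter literature does not
enumerate its exact feature set; this concrete set is a stand-in and is
labelled as such.

## LSTM classifier

Architecture: sequence input (1–3 envelope channels, raw m/s) → one LSTM
layer → fully connected → softmax over {young, elderly}.  Reference
hyper-parameters: 400 hidden cells, batch 128, Adam at initial learning
rate 1e-4 attenuated ×0.9 every 30 epochs, 150 epochs (the stopping rule is
not specified anywhere authoritative; 150 epochs lets the decay schedule
execute meaningfully), zero-padding per mini-batch to the batch maximum
length without masking, read-out at the last padded step.  Inference is
always per-sequence and unpadded, so a prediction cannot depend on batch
grouping; softmax ties break toward "young" (first class in the fixed
ordering).

The LSTM is implemented directly in numpy (single layer, full BPTT, Adam),
with uniform Glorot initialization, forget-gate bias 1, float32 arithmetic,
and global-norm gradient clipping at 1.0 — without clipping, training
intermittently explodes late in optimization.  Mini-batches group sequences
of similar length (`sort_batches`, on by default): with read-out at the last
padded step, large padding lets the forget gate wash out the cell state over
trailing zero-input steps and can stall learning entirely; length-sorted
batches keep padding to a few frames.  Optional flags (all off by default,
matching the reference description): `masking` (read-out at each sequence's
own final step), `standardize` (z-score channels with training statistics),
`class_weighting` (inverse-frequency loss weights for the 87/213 imbalance).

**Test-scale configuration.**  The automated tests and the acceptance
script run the reference schedule (lr 1e-4, ×0.9 every 30 epochs, 150
epochs) with 48 hidden units and batch 32 instead of 400/128.  This is the
package's documented reduced operating point for cohort-scale runs on
modest hardware; the toy-problem unit tests use still smaller networks.

## Evaluation protocol

Repeated hold-out: the cohort is split 7:3 (training size round(0.7·n), so
300 → 210/90), stratified by class by default (the reference protocol does
not say; stratification is the safer default for an 87/213 imbalance), the
classifier is retrained from scratch each trial, and accuracies are averaged
over the trials (30 in the reference protocol; the tests use 5 at the
documented test scale).  Whether the reference protocol retrained per trial
or resampled test sets around one model is ambiguous; this package retrains
per trial.  Confusion matrices pool all trials' test predictions and are
row-normalized with rows = predicted class.  When conditions are compared,
all conditions share the same per-trial split seeds (paired comparison).
Per-trial seeds, accuracies and test identifiers are stored in the report,
so every cell is re-derivable.

## Numerical choices and degenerate inputs

* Unbiased, normalized autocorrelation for period estimation; FFT-based.
* Envelope peak detection is O(bins) per frame via run-compression; exact
  ties (plateaus) are resolved to the leftmost bin deterministically.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  per-participant and per-trial seeds derive from a master seed via
  `SeedSequence` and stay below 2^31.  Fixed seeds give bit-reproducible
  datasets, training runs and reports.
* Degenerate guards: empty/single-class training sets, mixed channel
  counts, zero-length sequences, all-zero spectrograms, aliasing parameter
  sets, too-short recordings, and aperiodic recordings all raise
  informative errors rather than degrade silently.

## Known limitations

* The simulator's class contrasts are configuration, not epidemiology; the
  headline accuracies on synthetic cohorts say nothing quantitative about
  real young/elderly classification.
* The stance/swing kinematics are stylized (piecewise pulses, exact
  left/right symmetry, no double-support nuance); the Nyquist ceiling of a
  600 Hz / 24 GHz radar forces swing peaks well below physiological foot
  speeds, so limb cycle-averages cannot match the torso as they do in
  reality.
* Period estimation assumes near-symmetric gait (step period = half cycle);
  strongly asymmetric gaits would need the asymmetry modelled before the
  doubling rule is trustworthy.
* The numpy LSTM is single-layer and CPU-bound; it is sized for hundreds of
  sequences of a few hundred frames, not for large-scale training.
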
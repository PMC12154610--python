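# Methods

This note documents the models and procedures implemented in `gainlisten`,
the choices made where the design was genuinely open, and what the
desk-scale synthetic experiments do and do not establish.

## Cochlear front-end (`gainlisten.periphery`)

The periphery is a fixed (non-learned) map from a stereo waveform to a
cochleagram. Per ear:

1. FIR gammatone filterbank. Center frequencies are spaced uniformly on the
   Glasberg–Moore ERB-number scale, `ERBn(f) = 21.4·log10(0.00437·f + 1)`,
   with inclusive endpoints (defaults 40 Hz – 20 kHz, 40 channels). Each
   impulse response is a 4th-order gammatone
   `t^3 · exp(−2π·b·t) · cos(2π·cf·t)` with `b = 1.019·ERB(cf)`, truncated
   to 25 ms (`floor(0.025·fs)` taps — 1102 at 44.1 kHz) and normalized to
   unit envelope peak. Filtering uses center-aligned "same" convolution;
   edge artifacts are discarded by the middle-excerpt step below.
2. Half-wave rectification and power-law compression (exponent 0.3),
   emulating outer-hair-cell compression.
3. Low-pass resampling to 10 kHz with a Kaiser-windowed sinc kernel
   (width 64 zero-crossings, roll-off 0.94759 of the target Nyquist,
   β = 14.76965), applied zero-phase. For integer decimation factors the
   polyphase path is replaced by an equivalent FFT convolution with the
   same kernel (verified identical to 1e−14) for speed. This imposes the
   phase-locking limit of the auditory nerve.
4. The middle 2 s of the 2.5-s material is excerpted, avoiding onset/offset
   transients, giving a 2 (ears) × 40 (frequencies) × 20 000 (timesteps)
   nonnegative array at the default configuration.

The gammatone phase/normalization convention is not uniquely determined by
the literature; envelope-peak normalization was chosen, and the
channel-selectivity tests verify behavior against each filter's directly
evaluated magnitude response rather than against a particular gain
convention.

## Feature-gain networks (`gainlisten.gainnet`)

Each convolutional block is layer normalization → 2-D convolution → ReLU →
Hanning-weighted average pooling:

- **Layer normalization** normalizes each example by the mean and variance
  over all feature dimensions (C, F, T), with ε = 1e−5 and learnable
  scale/shift γ, β. γ and β default to per-channel shape (C, 1, 1); a
  full-shape (C, F, T) parameterization is selectable
  (`NetworkSpec.norm_param_shape="full"`). The per-channel default keeps
  the parameter count independent of the input duration; the statistics
  are identical in both cases.
- **Convolution** uses stride 1, no bias (redundant after normalization),
  "valid" boundaries in time (no zero-padding, so a kernel of extent n_t
  shrinks T to T − n_t + 1) and zero-padded "same" boundaries in
  frequency.
- **Pooling** convolves with a unit-sum 2-D Hanning kernel before
  subsampling to reduce aliasing. The kernel extent is 1 where the stride
  is 1 and 4·s for stride s > 1; the kernel is separable and is applied as
  two 1-D stages.

**Attention** is a per-stage sigmoidal gain. The cue is propagated through
the same blocks (shared weights, no gains on the cue path); its activation
is averaged over time into a memory m ∈ R^{C×F}; a gain map

    g = θ1 + (1 − θ1) · logistic(θ2 · (m − θ3))

multiplies the mixture activation at the same stage, broadcast over time.
This parameterization has limits {θ1, 1}: features strongly present in the
cue pass at unit gain, others are scaled by the learned bias θ1. An
alternative algebra, g = θ1 − (1 − θ1)·logistic(θ2·(m − θ3)) with limits
{θ1, 2θ1 − 1}, is selectable (`parameterization="shifted"`); the two
coincide at θ1 = 1. Gains are initialized to the identity
(θ1 = 1, θ2 = 1, θ3 = 0) so an untrained network is exactly a gain-free
network, which stabilizes early training; θ1's gradient is nonzero at the
identity, so the parameters do not stay stuck there. One gain triple is
learned per stage (cochleagram stage plus each block); per-feature gain
parameters are deliberately out of scope.

Control variants: `baseline` receives cue and mixture concatenated as a
4-channel input with no gains; `early-only` applies a single gain at the
cochleagram; `late-only` applies a single gain after the final
convolutional block. All variants collapse to the same gain-free pass at
θ1 = 1 (tested exactly).

The classifier head is flatten → fully-connected (with bias) → ReLU →
dropout (p = 0.5, training only) → linear → softmax. Argmax ties resolve to
the lowest class index.

Networks are trained with an in-repo reverse-mode autodiff core
(`gainlisten._tensor`, numpy/BLAS): convolution via one contiguous im2col
matrix per call (reused for the weight gradient; the input gradient is the
transposed convolution, computed by the same im2col path on the padded
output gradient). All gradients are verified against central finite
differences in the test suite, including the gain θ parameters through the
full dual-path (cue + mixture) graph.

## Spatial rendering (`gainlisten.spatial`)

Rooms are shoeboxes with log-uniform dimensions (3–30 m length/width,
2.2–10 m height); the listener is uniform subject to ≥ 1.45 m from every
wall and ≤ 2 m height. Each environment has a location grid of 72 azimuths
(5° steps) × 11 elevations (−40°…+60° in 10° steps; the elevation endpoints
are a package choice and configurable) × 2 distances (1.4 m fixed, plus one
drawn uniformly between 1 m and 0.1 m inside the wall along that ray) =
1584 locations.

Binaural rendering is parametric: a spherical head (radius 8.75 cm) with
the Woodworth ITD `(a/c)·(φ + sin φ)` split symmetrically across ears, a
broadband far-ear attenuation (6 dB × |sin az|), and a first-order
Butterworth low-pass head shadow on the far ear whose cutoff shrinks with
lateralization; the shadow filter is applied zero-phase so it does not bias
the ITD. Amplitude scales as 1.4 m/distance. Elevation changes neither cue
in parametric mode — a documented limitation; users needing
measured-room fidelity can pass a per-ear BRIR pair, which is convolved
directly. Rendering is linear, and midline/mirror symmetries are exact by
construction.

Precedence-effect stimuli render the signal at the lead location, render a
copy zero-padded by `floor(delay·fs)` samples (176 at 4 ms, 44.1 kHz) at
the lag location, and sum the binaural channels.

## Synthetic talkers and scenes (`gainlisten.scenes`)

The synthetic corpus emulates, at desk scale, the statistics the full-scale
task relies on:

- **Talkers** have an f0 drawn from one of two disjoint "sex-class" ranges
  (class A: 80–160 Hz, class B: 170–320 Hz) and a talker-specific spectral
  envelope (two formant-like Gaussian resonances, f1 ∈ 250–750 Hz,
  f2 ∈ 0.9–1.7 kHz, plus a spectral tilt of −9…−3 dB/octave).
- **Words** are fixed-duration segments (five words tiling 2.5 s by
  default) whose identity is carried by a word-specific
  amplitude-modulation rate (3–14 Hz), AM depth, and a drifting
  spectral-emphasis trajectory, all derived deterministically from a hash
  of the word label — so a word is recognizable across talkers. An
  utterance is the sum of harmonics of f0 shaped by these envelopes, with
  10-ms raised-cosine boundary ramps. The label of a clip is the word
  overlapping the 1-second mark of the middle 2-s excerpt.
- **Inharmonic** versions shift every partial above f0 by an independent
  uniform draw in ±30% of f0, rejection-sampled until all adjacent
  spacings are ≥ 30 Hz; the pattern is stored in units of f0 so the same
  pattern can be reapplied to the other utterances of a trial. (The
  alternative reading — shifts of exactly ±30% — is obtainable by
  supplying such a pattern explicitly.)
- **Whispered** versions replace the harmonic excitation with white noise
  high-passed by a second-order Butterworth (3-dB cutoff 1.2 kHz) whose
  zeros are shrunk to radius 0.95 (restoring a little low-frequency
  energy), then shaped by the same spectral envelope and AM; per-word RMS
  is preserved. The filter is designed at the stimulus rate and applied
  once, forward; its response is validated qualitatively (monotone
  high-pass, positive DC gain) rather than against any specific printed
  attenuation figures.
- **Noises**: speech-shaped noise imposes a reference clip's magnitude
  spectrum on white noise; pink noise uses a 1/f power spectrum.

Levels use a fixed digital reference of RMS 1.0 ≡ 100 dB SPL (arbitrary but
fixed; all SPL arithmetic is relative, and 50–70 dB sources stay in
well-conditioned float range). Mixtures scale the target against the summed
distractors to the requested SNR and are RMS-normalized to 0.02, as is the
cue.

**Scene generation** follows a seven-step draw: target talker/words; cue
from the same talker centered on a different word; distractor count uniform
on 1–6; speech/non-speech split uniform; speech distractors from other
talkers and noise distractors from the noise inventory; per-source levels
uniform 50–70 dB SPL; SNR uniform −10…+10 dB. The cue is always rendered at
the target's location; half the scenes co-locate all distractors with the
target; 10% of scenes are single-talker with an all-zero cue.
Augmentations: a random Butterworth band-pass (order 1–4, cutoffs 40–400 Hz
and 4–16 kHz, applied to cue or target with probability 0.5) and a
label-preserving time shift of up to 50% of the labeled word's duration.

## Training and evaluation (`gainlisten.training`)

Training is AdamW on softmax cross-entropy over the middle-word label, with
gains and features optimized jointly and the cochlear stage fixed. The
reference configuration (learning rate 5e−5, batch 288, dropout 0.5) is the
default `TrainConfig`; weight decay (0.01, applied to convolution and dense
weights only) and the early-stopping rule (no validation improvement for 3
epochs) are package choices where no reference value exists. Desk-scale
runs use learning rate 2e−3, batch 32, and a fixed 12-epoch budget with the
plateau rule disabled: on these small runs validation accuracy can sit at a
pre-cue-use plateau for several epochs before the gain path engages, and
stopping there would truncate an otherwise healthy run.

**Desk-scale study conditions.** The toy task uses an 8-word vocabulary and
four talkers (two per sex class, so that both same-class and
different-class talker pairs occur, as the representational analysis
requires); presentation is diotic, with exactly one speech distractor at
0 dB SNR, 10% silent-cue scenes, and no augmentations. The cochlear stage
is scaled down to 16 ERB channels over 50–1800 Hz at a 4 kHz audio rate,
with envelopes sampled at 125 Hz (the word-identity AM rates of 3–14 Hz
are well within this bandwidth), giving 2×16×250 cochleagrams. The default
toy network has three conv blocks (8/16/24 channels) and ~30k parameters.
These sizes were chosen once as the smallest configuration at which the
selection behaviors of interest are measurable on a single CPU; the
full-scale settings remain available through the same configuration
objects.

## Analyses (`gainlisten.analysis`)

- **Scoring**: a response is correct iff it matches any in-vocabulary word
  of the target transcript and a confusion iff it matches any
  in-vocabulary distractor word; the same function scores humans and
  models.
- **Thresholds (SRT)**: a second-order polynomial is fit by least squares
  to the performance-by-SNR curve (the across-subject mean when a subject
  matrix is given); the SRT is the crossing of the criterion level —
  either 50% of the curve's maximum ("fraction-of-max") or absolute 50% —
  preferring an in-span crossing with positive slope (psychometric
  monotonicity); out-of-span solutions are flagged as extrapolated.
  Uncertainty via bootstrap over subjects (default 10 000 resamples).
- **Interaction permutation test**: for a (subjects × A × B) threshold
  table, the statistic is the sum of squared interaction residuals
  `t_ij − μ_A(i) − μ_B(j) + μ_total` of the across-subject mean table; the
  null permutes each subject's cell labels independently (10 000
  permutations by default); p-values use the add-one convention and are
  never exactly zero.
- **Human–model similarity**: RMSE and squared Pearson correlation over
  aligned condition means; architecture comparisons use a two-tailed sign
  test over paired per-architecture scores plus the difference of means.
- **Locus of selection**: target-alone, distractor-alone, and mixture
  clips (diotic, RMS 0.02, mixed at 0 dB) are passed through the network
  with the same cue, and the flattened per-stage activations of the
  mixture are Pearson-correlated with those of the target and of the
  distractor; stages with constant activations are excluded with a count.
  Trials balance same-class and different-class talker pairs.

## What the synthetic experiments show — and what they do not

The generator reproduces the *structure* of the full-scale task (cued
selection among overlapping sources, word labels tied to the excerpt
midpoint, level/SNR statistics, spatial layout) but not natural speech:
spectra are far sparser and more stationary than real voices, there is no
coarticulation, reverberation defaults to anechoic, and the vocabulary is
tiny. Passing tests therefore establish that the implementation is
internally correct and that cue-driven gain attention *can* be learned and
measured in this pipeline — including above-chance cued recognition whose
direction reverses under cue swapping, and a trained-network
target-enhancement profile that differs from the random-weight control.
They do not establish human-level word recognition or quantitative
reproduction of full-scale behavioral results, which would require natural
speech corpora and GPU-scale training.

Because the toy talkers' spectra are sparse, a large part of the learned
selection acts already at the cochleagram stage for different-class talker
pairs; the late-stage enhancement signature is carried mainly by the
same-class pairs, where peripheral channel gains cannot separate the
talkers. This is why the representational analysis balances the two pair
types.

## Numerical choices

- float32 throughout the network (the autodiff core preserves dtypes;
  python scalars adopt the tensor's dtype, so the mixture path is never
  silently promoted to float64).
- Dropout masks and all stochastic draws come from explicit
  `numpy.random.Generator` objects; every public sampling function is
  reproducible from (config, seed), and evaluation-mode forward passes are
  bit-deterministic.
- Degenerate inputs fail loudly: all-zero waveforms cannot be level-set,
  silent distractors cannot be SNR-mixed, empty time axes cannot be
  averaged, missing factorial cells are not imputed.
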
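# Methods

## Model

The classifier maps a heartbeat to one of the four modeled AAMI
super-classes (NB, SVEB, VEB, FB) from two views of the same beat: the
fixed-length 1-D waveform and its CWT scalogram. Two feature stacks run
in parallel — three full-sequence LSTM layers (16/32/64 units) and three
convolutional blocks (16/32/64 filters; each block is 3×3 size-preserving
convolution + ReLU, 2×2 max-pooling with ceiling semantics, dropout 0.1,
then batch normalization) — and are *cross-fused* twice: the LSTM output
sequence is reinterpreted row-major as a grid whose column count equals
the current conv-map width, concatenated with the conv map along the
first spatial axis, and the fused map is routed into both branches (back
to a sequence for the next LSTM layer; directly into the next conv
block). The third-stage outputs are flattened and concatenated
(216 000 + 56 576 = 272 576 features) into dropout(0.1) → dense(128,
ReLU) → dense(4, softmax). The fusion rule forces equal unit/filter
counts per stage, which `ModelConfig` validates.

Design points that were genuinely open and how they were fixed:

* **Pooling semantics.** Output size is ⌈d/2⌉ (odd edges padded), the
  only convention consistent with the reference shape chain
  (100→50, 54→27, 135→68, 25→13); partial windows still take a real
  maximum because padding is −∞.
* **Concatenation axis.** First spatial axis, forced by the fused shapes
  (54 = 4+50, 135 = 108+27); a channel-axis reading of fusion is
  arithmetically incompatible with those shapes.
* **Reshape factorization.** Grid columns always equal the conv-map
  width (50, then 25 in the default chain); rows = T/cols, row-major.
  When T is not a multiple of the column count — which happens for
  reduced desk-scale configurations such as a 50-step sequence against
  14-wide maps — the sequence is zero-padded at the end to the next
  multiple before reshaping, and gradients to the padding are discarded.
  The default 200-step configuration is unaffected.
* **Head activation.** dense(128) uses ReLU; the output layer is the
  stated softmax.
* **Conv-block order.** conv+ReLU → pool → dropout → batch norm,
  following the block's listed composition.

### Implementation and its verification

The network is implemented directly in NumPy (float64, channels-last),
including backpropagation: BPTT for the LSTM (fused weight matrix over
[x_t, h_{t−1}], gate order input/forget/cell/output, forget-gate bias
initialized to 1), im2col convolution, argmax-routed pooling gradients,
standard batch-norm backward, inverted dropout, and Adam with
bias-corrected moments (β₁ = 0.9, β₂ = 0.999 — conventional defaults).
Weights use Glorot-uniform initialization under a settable seed.
Correctness is established two ways in the test suite: every layer and
the assembled network pass directional finite-difference gradient
checks, and the LSTM layer is checked step-by-step against a separate,
deliberately naive implementation of the gate equations
(f, i, o = σ(W[h, x] + b); c = f⊙c′ + i⊙tanh(W_c[h, x] + b_c);
h = o⊙tanh(c)).

The trainable-parameter count is computed both by summing instantiated
arrays and by the closed-form per-layer formulas (conv k_h·k_w·C_in·F+F;
LSTM 4((I+H)H+H); batch norm 2C; dense I·O+O); the two must agree
exactly. The default model has 34 946 148 parameters, dominated by the
272 576→128 dense layer (34 889 856).

## Preprocessing

Baseline wander is the cascaded median estimate: a 200 ms filter
followed by a 600 ms filter, subtracted from the raw signal. Window
widths are converted to odd sample counts (round(w·fs), +1 if even) so
the median is a sample value; edges are handled by boundary-inclusive
reflection (the brute-force sliding-median oracle in the tests uses the
same convention). Segments span ⌈Δt₁·fs⌉ samples before to ⌈Δt₂·fs⌉
after each annotated R-peak — (Δt₁+Δt₂)·fs + 1 samples, 289 at the
defaults — and are linearly resampled to `target_len` (200). The
resampling step is this package's reconciliation of the 289-sample
analysis window with the network's length-200 input; both lengths are
configurable. Beats whose window crosses a record boundary are dropped
and counted, not padded. Each segment is z-scored (sd floor 1e−8; a
no-normalization mode exists) so the network sees amplitude-invariant
morphology.

## CWT scalograms

Discrete convention, fixed and shared with the test oracle: time in
sample units, C[i, b] = a_i^(−1/2) Σ_n w_n x[n] ψ((n−b)/a_i) with
trapezoid weights w over the signal's own support, evaluated for every
integer shift by FFT convolution with the wavelet sampled on the full
support (no kernel truncation). An independent brute-force quadrature
oracle must agree to 1e−6 relative error.

Wavelets follow their standard named definitions — gausN is the N-th
derivative of a Gaussian normalized to unit L2 norm, mexh the Mexican
hat (σ = 1), morl the cosine-modulated Gaussian (ω₀ = 5) — because the
alternative closed forms circulating for these names are mutually
inconsistent. Center frequencies are measured from the FFT peak of the
sampled wavelet (cross-checked against PyWavelets' estimates in the
tests) rather than hard-coded. The scale grid is 100 *linearly* spaced
values from 2.16 to 216; the scalogram intensity is the magnitude |C|
(configurable in principle to real part or power), bilinearly resized to
100×100 and min–max normalized per image, with zero-range images
(within float wobble) mapping to all-zero.

## Evaluation protocol

Metrics are one-vs-rest per class from the confusion matrix: ACC, PPV
(precision), SE (recall) and F1, in percent, plus unweighted macro
averages; zero-denominator ratios are reported as 0 and flagged.
Splitting is stratified 80/20 and cross-validation stratified 10-fold
(scikit-learn's samplers) so the sub-1% fusion class appears in every
partition; argmax ties break toward the lower class index. No class
weighting or resampling is applied anywhere — the architecture is the
imbalance treatment under study. Reported tables round to two decimals.

## Synthetic data

The generator emulates 360 Hz single-lead ECG as sums of Gaussian bumps
(P, Q, R, S, T) with class-specific geometry: NB is the reference
morphology; SVEB has a flattened early P wave and arrives after a
0.7-shortened RR interval; VEB has a wide (≈3× sd), high-amplitude QRS,
no P, and a discordant T; FB is the 0.5/0.5 convex combination of the NB
and VEB templates. Records add sub-0.5 Hz sinusoidal baseline drift
(default 0.15 mV at 0.3 Hz), white noise (default sd 0.03 mV), 5% RR
jitter around 75 bpm and 5% per-beat amplitude jitter; defaults follow
what ambulatory recordings plausibly look like at this level of
abstraction, and the default class mix (89.5 / 2.7 / 7.0 / 0.8%) mirrors
the skew of real arrhythmia databases. Everything is deterministic given
the seed.

What the generator does *not* emulate — inter-patient morphology
variation, electrode artifacts, rhythm context beyond SVEB prematurity,
and the full diversity within each AAMI super-class — bounds what
passing tests mean: they demonstrate that the pipeline, the network and
the protocol are implemented correctly and can learn separable
morphology under realistic imbalance, not that the model attains any
particular accuracy on clinical data. By construction the class
templates are nearest-centroid separable, so the learning tests measure
the pipeline rather than generator difficulty.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
the learning check trains a reduced network (4/8/8 units and filters,
50-sample beats, 28×28 scalograms, ≈57 k parameters) for 10 epochs on
2 000 synthetic beats with the default imbalance (macro-F1 > 0.90 on the
held-out 20%); cross-validation and sweep drivers run on still smaller
fixtures. The full-size model (200-sample beats, 100×100 scalograms,
34.9 M parameters) is built and traced — and one sample is pushed
through it — but never trained here; its published-scale training run
requires the real database and GPU-class resources and is out of scope.

## Known limitations

* Training the full-size model in NumPy on one CPU is impractical; the
  implementation is exact but not performance-tuned beyond vectorized
  batching and FFT convolution.
* WFDB support covers single-segment records, signal formats 16 and
  212, and one annotator — enough for MIT-BIH-style directories, not
  the full WFDB specification.
* The real Morlet used here is the non-analytic cosine form; complex
  analytic wavelets are not implemented.
* SVEB vs NB is intentionally the hardest pair in the generator (the
  distinction is mostly P-wave and prematurity), and small training sets
  show exactly that confusion.
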
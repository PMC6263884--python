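# Methods

This note documents the models, the numerical choices, and the synthetic
data design behind `skitech`, and what the shipped tests do and do not show.

## Problem setting

A skier wears up to 17 inertial motion trackers; each tracker's gyroscope
reports angular velocity on three local axes at 240 Hz, giving up to 51
channels. Skiing techniques are cyclic: one cycle is a full repetition of
the limb/pole motion pattern. The classification unit is the cycle, and the
pipeline is a chain of

    label-based noise excision -> peak segmentation -> fixed-length
    resampling -> tensor -> classifier -> per-split confusion matrices.

Angular velocity is treated as rad/s throughout, but no stage depends on an
absolute unit: the filter and peak criteria are scale-free (prominence is a
fraction of the filtered signal's interquartile range), resampling is
linear, correlations are scale-invariant, and the network is trained on raw
values whose scale the max-pooling layers largely absorb. A global unit
mistake therefore cannot silently change results.

## Segmentation

**Filtering.** Cycle boundaries are found on one reference channel (default
`left_lower_leg_gyr_z` — the shin's mediolateral-plane rate, which swings
once per stride in every technique). The channel is low-passed with a
4th-order Butterworth filter applied forward and backward
(`scipy.signal.sosfiltfilt`), so the phase response is exactly zero and
peak positions are not lagged. The two passes square the magnitude
response: gain is 1/(1+(f/fc)^8), i.e. 1/2 at the cutoff.

**Cutoff interpretation.** The configured cutoff of 0.007 is read as a
fraction of Nyquist (0.84 Hz at 240 Hz). Read as an absolute 0.007 Hz the
filter would pass less than two events per five minutes, which cannot
expose per-stride peaks; 0.84 Hz sits just above typical stride rates
(a 333-frame cycle at 240 Hz is 0.72 Hz), so the fundamental passes while
every harmonic and the broadband noise are crushed — precisely what makes
the peak picker robust. An `absolute_hz` mode is provided for sensitivity
analysis.

**Peak criteria.** `scipy.signal.find_peaks` with a minimum peak distance
of half the fixed cycle length (166 frames) and a minimum prominence of
0.3 × IQR of the filtered channel. Both are configurable; the defaults
prevent double-peaking on harmonic-rich strides and are invariant to
amplitude scale. Maxima are used; polarity is configurable by negating the
reference channel upstream. A (near-)constant filtered channel (IQR below
1e-8 of its magnitude) raises a "no cycles" error rather than detecting
float ripple.

**Cycle extraction.** Frames labeled 0 (start/end), 9 (descending), TURN,
or nothing (transitions) are excised first; peaks are then detected within
each remaining segment independently, so no cycle can bridge an excised
gap. Cycles are the half-open frame ranges between consecutive peaks;
the partial cycles before the first and after the last peak are discarded.

**Resampling.** Each raw n-frame cycle is resampled to 333 frames with
`scipy.signal.resample_poly` (anti-aliasing FIR, Kaiser window), i.e. at a
rate of (333/n) × 240 Hz. Resampling operates on *raw* values — the
filtered signal exists only for peak localization — because the network is
meant to extract its own features from unsmoothed data. To suppress FIR
edge transients on short cycles, the cycle is mirror-extended by its full
length on both sides before filtering and cropped afterwards; with a full
mirror the crop offset is exactly 333 samples (n·(333/n) is integral by
construction), so no fractional-sample shift is introduced. 333 is the
assumed mean cycle length of the motion regime and is configurable.

**Zero-phase boundary transients.** Forward-backward filtering distorts
the first and last ~1–2 s of a segment (the filter's settle region), which
can shift a peak that sits very close to a segment edge by several frames.
This only affects edge peaks; the partial-cycle discard means such peaks
bound at most the first/last extracted cycle. The segmentation oracle
therefore measures boundary recovery in the segment interior.

## CNN-LSTM classifier

Layer stack for an input cycle of shape (333, C):

    Conv1D(64 filters, kernel 20, valid) -> ReLU
    Conv1D(64 filters, kernel 10, valid) -> ReLU
    MaxPool1D(4)                                  # 333 -> 314 -> 305 -> 76
    LSTM(300, full sequence) -> Dropout(0.2)
    LSTM(200, last state)    -> Dropout(0.2)
    Dense(8) -> softmax

The convolutions fuse all C channels in a single step and extract local
cross-channel interactions; max-pooling buys tolerance to time/amplitude
scale; the stacked LSTMs model the ordering of the pooled features; the
final hidden state feeds the softmax. Training: categorical cross-entropy,
Adam (lr 1e-3, β 0.9/0.999, ε 1e-7) with global-norm gradient clipping at
5.0, 12 epochs, batch 40, no early stopping and no class reweighting
(imbalance is surfaced in per-class reporting instead).

Choices the architecture description leaves open, resolved as the standard
ones: ReLU after each convolution, valid (no) padding, the first recurrent
layer returns its full sequence so the second can stack on it, the second
returns only its last hidden state.

The network is implemented directly in NumPy (float32, BLAS matmuls):
convolution as an im2col view plus one matrix product, LSTM with exact
backpropagation through time, inverted dropout. One
`numpy.random.Generator` seeded by a single integer drives initialization
(Glorot-uniform input weights, orthogonal recurrent weights, forget-gate
bias +1), epoch shuffling and dropout masks in a fixed order, so a fit is
bit-reproducible for a given seed on a given platform. Analytic gradients
are verified against central differences in the test suite. At these
problem sizes (hundreds of cycles, ~10^6 parameters) a fit takes tens of
seconds on one CPU core.

## KNN baseline

Each cycle is summarized by the Pearson correlation of every unordered
channel pair, in lexicographic order, plus one scalar: C(C−1)/2 + 1 values,
1276 for 51 channels. Correlations of constant channels are 0 by
convention. The appended scalar is the cycle's pre-resampling length
normalized by twice the target length and clipped to [0, 1] — a bounded
tempo cue, the one per-cycle quantity that survives resampling only in the
metadata; it can be replaced by a constant to ablate tempo information.
Classification is Euclidean k-nearest neighbours (default k = 5,
configurable) with majority vote; a tied vote is resolved by the nearest
neighbour carrying one of the tied labels. Neighbour search is delegated to
scikit-learn; the voting rule is implemented here because library
tie-breaking differs.

## Evaluation protocols

`loso_splits` holds out one subject at a time: training cycles are the
*other* subjects' flat-course cycles only; test cycles are everything from
the held-out subject, flat and natural. Natural-course data is never used
for training in any shipped protocol. Confusion matrices are always 8×8
(rows = true, columns = predicted, class codes 1–8 in order); classes
absent from a split keep their zero rows so sub-tables stay
shape-compatible. Mean accuracies over split cells are unweighted by
default, with a cycle-weighted variant available because cells can differ
greatly in size. The cross-style fraction is the confusion mass in the
classical×skating and skating×classical blocks divided by the total cycle
count. Sensor ablation column-subsets the stored tensors, so all five
configurations share identical cycle boundaries (segmentation always ran on
the reference channel of the full recording).

## Synthetic data design

The simulator emulates the *structure* that matters for testing this
pipeline, not skiing biomechanics:

- **Templates.** Each technique is a fixed set of 3-harmonic waveforms per
  channel (amplitudes and phases), constants of the package. Extremity
  channels (hands, feet) are fully class-specific with unit-scale
  amplitudes; mid-body channels (arms, legs, shoulders) are a 0.75/0.25
  blend of a style-shared waveform and a class-specific one at 0.6 scale;
  torso/pelvis channels are a 0.9/0.1 blend at 0.35 scale. Hence the class
  signature lives on the extremities, mid-body trackers add little beyond
  them, and a pelvis-only configuration is genuinely information-poor —
  mirroring the known physiology (extremity motion is the most exaggerated;
  the pelvis tracks the body's overall motion).
- **Confusable pair.** The push-off analog (code 2) is derived from the
  double-poling analog (code 4) with similarity 0.9: all non-extremity
  channels are copied, extremity harmonic coefficients are interpolated
  with weight 0.9. At similarity 1 the templates coincide; at 0 they are
  independent. 0.9 is chosen so the pair is the dominant — but not total —
  source of confusion, the intended analog of two techniques whose motions
  differ only in limb dynamics; the test suite verifies that confusion
  rises monotonically between similarity 0.1 and 0.9.
- **Reference channel.** Every template carries a unit-amplitude
  fundamental with zero phase on the reference channel, so its filtered
  peak marks the cycle start and generator boundaries are a valid oracle
  for the peak detector.
- **Subjects.** Per-tracker amplitude gains uniform in [0.7, 1.3], a
  personal tempo (mean cycle length uniform in [300, 366] frames, times a
  per-technique factor in [0.90, 1.10]), per-cycle length jitter of 5%, and
  additive white noise with σ = 0.1 rad/s on every channel (absolute, so
  low-amplitude channels have poorer SNR).
- **Files.** Technique blocks are separated by noise: low-amplitude
  broadband wander for turning segments on flat courses, low-frequency
  drift for descents on natural courses, short unlabeled transition gaps,
  and label-0 wander at the ends. Natural-course recipes omit the
  free-skate and push-off analogs, reproducing the class-imbalance regime
  of real course preferences.
- **Determinism.** One integer seed feeds per-file `SeedSequence` streams
  ([seed, 9000, file_index]), so datasets are reproducible file by file.

**Cycle-count fixture.** A 24-file census (3 subjects × 8 techniques, one
single-technique flat file each) with per-file cycle counts fixed at the
package's reference table (row sums 960/568/539, total 2067). Each file
renders count+2 cycles because peak-to-peak segmentation discards the two
partial end cycles; the pipeline then recovers exactly the tabulated count
for any seed, making the fixture a deterministic bookkeeping check of the
whole segmentation chain.

**Default study design.** 3 subjects × (flat classical, flat skating,
natural classical, natural skating) files, 12 rendered (10 segmented)
cycles per technique block: ~420 cycles, of which each LOSO split trains on
160. This size keeps a full 3-seed LOSO experiment within minutes on one
CPU core while leaving the qualitative structure (style separation,
confusable pair, sensor-configuration ordering) stable across seeds.

## What passing tests do and do not show

The synthetic waveforms are low-order harmonics with stationary templates;
real gyroscope data has richer spectra, within-file drift, sensor artifacts
and far larger within-class variability. Passing the end-to-end checks
shows the *pipeline* is correct and that the classifier recovers the
structure the generator encodes (styles separable, confusable pair
confused, extremity channels decisive, more training subjects helping); it
does not certify any particular accuracy on real skiing data. Absolute
accuracies on the synthetic design are optimistic relative to field data.

## Known limitations

- Turning/descending segments must be labeled; they are excised, not
  detected.
- Accelerometer and magnetometer channels are out of scope.
- The KNN baseline's tempo feature makes it unrealistically strong when
  techniques differ in cycle length; disable it (constant mode) to compare
  waveform information alone.
- Training determinism is per-platform (BLAS reduction order may differ
  across builds).
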
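# Methods

`pcgseg` segments phonocardiogram (PCG) recordings into the four cardiac
phases — S1, systole, S2, diastole — by per-sample sequence labeling.  This
note records the model, the numerical choices, the synthetic data the tests
rely on, and the limits of what those tests demonstrate.

## Signal model and conditioning chain

A PCG is a mono pressure signal dominated by two transients per heart
cycle: S1 (atrioventricular valve closure, ~100–150 ms) and S2 (semilunar
valve closure, ~60–100 ms), both with most of their energy between roughly
60 and 150 Hz.  The intervals between them (systole, then the longer
diastole) are comparatively quiet.  The feature fed to the labelers is a
smooth "activity" trace computed by:

1. **Bandpass** — 4th-order Butterworth, 60–150 Hz, applied forward and
   backward (zero phase) so burst onsets are not shifted relative to the
   sample-aligned labels.  Cutoffs at or above Nyquist are a configuration
   error.
2. **Normalisation** — symmetric min–max to [−1, +1] (default).  The plain
   [0, 1] min–max map is available as `normalize.mode=minmax`.  The
   symmetric map is idempotent and affine-invariant; constant signals are
   rejected (zero range).
3. **First intrinsic mode function** — empirical mode decomposition (below)
   with 3 levels; the first IMF isolates the fastest oscillation, i.e. the
   valve transients themselves, and discards residual baseline drift.
4. **Envelope** — magnitude of the analytic signal, realised by a
   200-tap FIR Hilbert transformer (below).
5. **Optional decimation** — anti-aliased integer decimation of the
   envelope.  The envelope is band-limited to a few tens of Hz, far below
   the raw signal band, so moderate decimation is essentially lossless for
   the labeling task while shortening model sequences proportionally.
   Default is 1 (off).

All stages preserve length; the chain output is non-negative (a magnitude,
with anti-aliasing ringing clipped at zero).

## Empirical mode decomposition

Sifting follows the classical scheme: cubic splines through the local
maxima and minima form upper/lower envelopes, their mean is subtracted,
and the subtraction repeats until the iterate satisfies the two IMF
criteria — extrema and zero-crossing counts differing by at most one, and
a spline mean envelope within 5% of the signal's amplitude range — with a
Cauchy-style stopping criterion SD = Σ(d_prev − d)²/Σd_prev² < 0.2 and an
iteration cap of 100 guaranteeing termination.  Both the SD condition and
the IMF check must hold before an IMF is accepted, which is what makes the
package-level invariant "every returned IMF passes the criteria" hold.

Numerical details:

- **Extrema** are detected by strict sign change of the first difference;
  plateaus contribute a single extremum at their midpoint (deterministic
  tie-break).
- **Boundaries**: two extrema at each end are mirrored about the first and
  last samples before spline fitting, limiting end swings.
- **Degenerate inputs**: a monotone or constant signal cannot support
  envelopes; decomposition stops and the residual is the signal itself.
  `first_imf` then passes the input through with a warning so batch
  pipelines survive silent stretches.
- **Reconstruction** Σ IMF + residual equals the input to machine
  precision by construction (each sift returns `(imf, x − imf)` exactly).

Because sampled extrema sit up to half a sample off the true peaks, the
mean envelope of a sampled sinusoid carries a small systematic ripple
(~10⁻³ of the amplitude at 30+ samples per period); sifting fidelity
statements in the tests account for this discretisation floor.

## Analytic-signal envelope

The envelope is |x + j·H(x)| with H the Hilbert transform.  The default
backend realises H as a 200-tap equiripple FIR transformer (antisymmetric,
passband 0.01–0.49 of the sampling rate).  Its group delay of 99.5 samples
is half-integer, so the in-phase branch is a matching 200-tap windowed-sinc
fractional-delay filter; both branches then share the same delay and the
magnitude is exact up to the design ripple (<0.1% in band).  Inputs are
reflect-padded so the stated edge region (~one filter length per end) is
the only place the envelope degrades.  An FFT-based backend
(`scipy.signal.hilbert`) is available and agrees with the FIR realisation
within 2% away from the edges; only the magnitude is consumed downstream,
so the sign convention of the imaginary part is immaterial.

## Annotation tables and labels

Region tables are 1-based, with consecutive rows sharing their boundary
sample and classes cycling S1 → systolic → S2 → diastolic.  A shared
boundary sample belongs to the **later** region, and the final row claims
its own end sample; under this convention a table ending at limit N
expands to exactly N per-sample labels and the expansion/run-length-
collapse pair is an exact bijection on valid tables (property-tested).
One consequence: a final region of exactly one sample is unrepresentable
(its row would have start = end); the synthetic generator's truncation
logic merges that sample into the preceding region.

Training windows are consecutive, non-overlapping, `round(window_seconds ×
rate)` samples long, with a sub-window remainder dropped.

## Sequence labelers

Three architectures, each a single recurrent layer over the scalar
envelope feature followed by a time-shared linear layer onto the four
classes and a softmax:

- **GRU** — update/reset-gate cell, forward direction only;
- **BiGRU** — forward and backward GRU, states concatenated per step;
- **BiLSTM** — bidirectional LSTM with separate cell state.

The gate arithmetic is spelled out in `models/cells.py` one step at a
time (bias-free mode matches the textbook equations exactly and is what
the oracle tests pin down); the batched training path in `models/nets.py`
reproduces it to machine precision and adds hand-derived backpropagation
through time, checked against finite differences.  Training minimises
per-time-step categorical cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999).
Initialisation is seeded Glorot-uniform; LSTM forget-gate biases start at
1 (the standard remedy for early memory wash-out).  Everything — the
record split, parameter draws, epoch shuffles — derives from one seed, so
training is bit-reproducible on a fixed thread count.

Defaults follow the study regime: 200 hidden units, learning rate 0.001,
minibatch 16, 70/30 train/test split **by source record** (window-level
splits would leak near-identical neighbouring heart cycles), 300 epochs
for the GRU and 200 for the bidirectional models.  Prediction is the
per-step argmax, ties resolved toward the lower class index in the fixed
order (S1, systolic, S2, diastolic).  A trained model stores a fingerprint
of the preprocessing configuration and refuses features produced by a
different chain.  No post-hoc smoothing or duration model is applied to
the label stream.

## Evaluation

Every sample is scored (no onset-tolerance windows).  Per class,
one-vs-rest sensitivity, specificity, precision and F1 are computed from
the 4×4 confusion matrix; the summary row macro-averages them, while
overall accuracy is micro (trace/total).  Group reports (per site or per
record) are pooled into an "ALL" row by summing confusion matrices, never
by averaging group metrics.  A class absent from a group yields missing
values excluded from macro means — not 0 or 100, which would silently bias
them.

## Synthetic phonocardiograms

The generator emulates exactly the structure the pipeline assumes:

- Gaussian-amplitude-modulated sinusoidal bursts for S1 (default 120 ms at
  80 Hz, amplitude 1.0) and S2 (90 ms at 110 Hz, amplitude 0.8 — S2
  slightly quieter, as at most auscultation sites), with 10% per-burst
  amplitude jitter and random carrier phase;
- quiet systolic/diastolic intervals, with optional band-limited murmur
  noise in either;
- systole (S1 onset through systolic end) occupying 35% of the nominal
  cycle at the configured heart rate (default 60 bpm); per-cycle rate
  jitter (default 5%) multiplies the diastolic duration only, since
  diastole physiologically absorbs most rate variation;
- additive white sensor noise at a configurable SNR (default 20 dB —
  a clean but not noiseless bedside recording).

Default sampling rate is 1000 Hz for desk-scale work; 4000 Hz mimics the
source corpora.  What the generator does **not** model: detailed valve
acoustics, S3/S4 and pathological sound taxonomies, respiration
modulation, recording artifacts, or inter-patient spectral variability.
Passing the end-to-end benchmark therefore demonstrates that the pipeline
machinery — conditioning, learning, inference, scoring — works and that
bidirectional context genuinely helps on this task structure; it does not
certify clinical-grade accuracy on real auscultation data.

## Reference benchmark

The full study regime (three corpora at 4000 Hz, 200 hidden units,
hundreds of epochs, training times in the thousands of minutes) is far
beyond one workstation.  The package's reference experiment
(`pcgseg.benchmark`) keeps the structure at desk scale: 100 synthetic
records of 20 s at 1000 Hz (heart rates spread ±10% across records),
conditioned with the standard chain plus envelope decimation by 5 (feature
rate 200 Hz, 400-step windows), split 70/30 by record, and the three
architectures trained at a matched budget of 50 hidden units and 30
epochs.  At 200 Hz a one-sample boundary error costs 0.5% of a cycle, so
per-sample accuracy remains sensitive to real segmentation quality.
Reported quantities: held-out per-sample accuracy and macro-F1 per
architecture, and whether the ranking BiGRU ≥ BiLSTM ≥ GRU holds.  In
development runs the margin is wide (BiGRU ≈ 99.7% held-out accuracy,
BiLSTM ≈ 99.0%, GRU ≈ 94%), with the unidirectional GRU penalised mainly
at phase onsets it cannot anticipate.

## Known limitations

- EMD is the plain sifting procedure; no ensemble variants (EEMD/CEEMDAN),
  so mode mixing on real noisy recordings is possible.
- The FIR envelope degrades within ~200 samples of the record ends.
- Raw argmax label streams need not respect the cyclic phase grammar;
  collapsing them to region tables warns rather than repairs.
- Training is CPU-bound NumPy: fine at benchmark scale, slow at the full
  study scale.
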
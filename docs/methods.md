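# Methods

This note records the model, the synthetic data it is validated on, and the
numerical and design choices that were genuinely open, in enough detail to
re-derive or challenge any of them.

## Pipeline and model

Continuous 8-channel EEG is band-pass filtered to 4–40 Hz with a 3rd-order
Butterworth IIR filter applied forward–backward (zero phase, so epoch
windows stay aligned with cue onsets; the squared magnitude response is the
effective gain), then decimated to 250 Hz with an anti-aliasing FIR
(polyphase) stage — FIR rather than the Chebyshev default so that DC and
passband gain are preserved exactly. Epochs are the first 2 s of each task
block, `[onset, onset + 2 s)`, giving 500 samples per channel.

**OVR-CSP.** Three one-versus-rest common-spatial-pattern problems (left,
right, rest against the pooled other two classes, in that fixed order) are
solved as generalized symmetric eigenproblems `R₁p = λR₂p` via
`scipy.linalg.eigh`. Per-trial covariances `XXᵀ` are trace-normalized before
averaging, which makes the filters invariant to global amplitude scale.
Eigenvalues are sorted descending, ties broken by input order, and each
eigenvector's sign is fixed so its largest-magnitude entry is positive.
Only the *top two* eigenvectors of each problem are kept (not the
conventional top+bottom pair) — this is the architecture as designed, kept
deliberately; the filters stacked in class order form `Z ∈ ℝ^{6×8}`. A
near-singular `R₂` is ridged by `1e-9·trace(R₂)/c·I` before solving.

**Network.** The classifier consumes `S = ZX ∈ ℝ^{6×500}`:

1. *Spatial self-attention* over the six feature-channel time vectors with
   square `500×500` projections `W_q, W_k, W_v` (the key length `d = 500`
   is the epoch length, which forces this reading of "input vectors"),
   scaled dot-product scores, row-softmax, convex mixing of the value
   vectors; dropout 0.3 on the output in training.
2. *Patch embedding*: a 1-D convolution along time per feature channel
   (2 filters, kernel 51, stride 1, valid) and a 2-D convolution spanning
   all six channels (10 filters, kernel 6×5, stride (1, 5), valid, depth 2)
   — the unique simple stride/padding choices that produce 10 patches × 90
   samples from a 6×500 input. **Each convolution is followed by an ELU.**
   The ELU is load-bearing: the head averages over time, and the
   time-average of any purely linear (or convex-mixture) transform of a
   zero-mean oscillation is ~0 regardless of its amplitude, so a
   nonlinearity between the convolutions and the pooling is what makes the
   pooled features sensitive to band *power* — the physical quantity
   (event-related desynchronization) that distinguishes the classes. ELU is
   the standard choice in EEG convolutional networks. `conv_activation=
   "linear"` switches it off for ablation; that variant trains to chance.
3. *Temporal multi-head attention*: the 10 patches are split in order into
   5 consecutive pairs `E_i ∈ ℝ^{2×90}`; each head applies scaled
   dot-product attention with `2×2` projections and key length 90 (the
   per-stage key length resolves the generic `√d_k`); head outputs are
   concatenated row-wise and mixed as `F = W_o·Concat` (`W_o ∈ ℝ^{10×10}`;
   the left-multiplication is the only dimensionally consistent order);
   dropout 0.5 on `F` in training.
4. *Head*: mean over the 90-sample axis; a log transform of the pooled
   10-vector (floored at 10⁻⁶) — band-power-like statistics are
   multiplicative, and the log is the standard treatment of variance-type
   EEG features (as in CSP log-variance classifiers); feature-wise
   normalization against training-set mean/variance (the inference form of
   batch-type normalization; the statistics are data constants estimated
   once per fit, never gradient-optimized, so the forward pass stays a
   pure function) with a learned per-feature gain/shift; then an affine
   map to 3 logits, softmax, cross-entropy loss. "Normalization" was read
   as *batch-type* rather than per-sample layer normalization
   deliberately: standardizing across the 10 features of each sample
   erases the pooled vector's overall level and contrast, which are
   exactly the statistics separating rest (all feature channels loud)
   from imagery (specific channels quiet) — measured on synthetic
   sessions, layer normalization costs ~8 accuracy points against the
   identical pipeline with feature-wise normalization. Prediction ties
   break toward the lowest class index via `argmax`. No positional
   encoding anywhere, following the architecture's silence.

Dropout applies to stage *outputs*, not attention weights. With dropout off
the forward pass is a pure function; all tests of numerical equivalence run
in evaluation mode and float64.

The forward pass, analytic backpropagation through every stage, and Adam
are implemented in NumPy (`tstn_bci.nn`); convolution forward/backward use
FFT convolution and BLAS-shaped contractions. Gradient correctness is
verified against central finite differences (1e-5 relative) and the whole
forward pass against a straight-line loop implementation (1e-8).

## Training

Adam, learning rate 2·10⁻⁴, batch size 50, cross-entropy; a stratified 10 %
hold-out drives early stopping on validation loss (default patience 20,
max 100 epochs; the parameters from the best epoch are restored). Stated
cross-validated results use stratified 10-fold CV with the full stack (CSP
bank included) refit on each fold's training split.

Where the training recipe was open, the package's choices are:

- **Input scale.** CSP features are divided by the training set's median
  per-epoch RMS, fixing the ELU operating range independent of recording
  gain.
- **Initialization.** Attention projections start near identity
  (`I + 0.01·U(−1,1)`), so the untrained network is approximately a
  pass-through. The two 1-D kernels start as a quadrature pair of Gabor
  atoms centred at 10.5 Hz (the mu-band centre at 250 Hz) and the ten 2-D
  filters as channel-selective positive time windows plus small noise:
  with these, the pooled 10-vector approximates the per-feature-channel
  rectified band amplitudes from the first step, and training refines a
  working band-power representation instead of having to discover one.
  The final affine map starts at zero (uniform initial probabilities) and
  the normalization gain at 4, which shortens the time for the fixed-step
  Adam updates to reach decision-relevant logit scale.
- **Layer-group learning rates.** The base rate is applied with multipliers
  {attention 0.02, patch embedding 2, head 10}. Adam moves every parameter
  ~lr per step regardless of layer size, so at a uniform rate the three
  250k-parameter spatial projections memorize a few-hundred-trial session
  within ~30 epochs while the head is still converging; on a held-out fold
  of the 900-epoch synthetic calibration design this collapses accuracy to
  ~0.63 against a CSP log-variance oracle ceiling of ~0.90. With the
  multipliers the network reaches ~0.89–0.90 on the same split. The
  multipliers are constructor parameters; setting all three to 1 restores
  a uniform rate.
- **Continual steps** warm-start from the current parameters and fine-tune
  on the cumulative pool (initial epochs + all previously selected trials)
  rather than retraining from scratch on new trials only: cumulative
  warm-starting is the reading of "continually train" that avoids
  catastrophic forgetting. The CSP bank is refit on the current pool at
  every stage so the features stay matched to the data the network is
  tuned on. Per-stage test metrics are computed before the update, which
  is what a deployed system would have observed.

## Synthetic sessions

The generator emulates the two session designs: AO+MI calibration sessions
(default 300 trials, 150 left / 150 right; each trial is two AO+MI blocks
of 2 s and one MI block of 2 s, each preceded by a rest period drawn
uniformly from 5–7 s) and MI-FB feedback sessions (default 150 trials,
50 left / 50 right / 50 rest; 5–7 s preparation + 3 s imagery block, of
which the classifier epochs the first 2 s). Rest-class training epochs for
calibration sessions are the final 2 s of each trial's first rest period —
the window most distant from task activity; the per-trial MI blocks form
the held-out feedback-free MI test set.

Per channel the signal is: a mu-rhythm oscillation + `1/f` background
(default 2 µV RMS in 4–40 Hz, exponent 1) + white noise (1 µV RMS).
The mu rhythm is a constant-amplitude sinusoid whose instantaneous
frequency wanders slowly around 10 Hz (Gaussian drift, sd 0.75 Hz,
correlation time 0.2 s). This narrowband-FM form was chosen over a pure
fixed-frequency sinusoid deliberately: with a shared fixed frequency all
channels are mutually coherent, and any spatial projection (CSP or
attention mixture) acquires per-trial interference cross-terms that do not
decay with epoch length — an artifact real EEG does not have, and strong
enough to cap even an ideal band-power classifier near chance. The drift
makes channels incoherent and the phase at any cue onset random (so no
phase-locked feature exists), while the constant amplitude keeps
single-trial band power nearly deterministic, which is what makes the
ERD calibration checks tight. The drift sd is kept at 0.75 Hz so 2σ
excursions stay inside the flat part of the 8–13 Hz analysis band.

ERD is a multiplicative amplitude envelope: during a task block of class
`c`, channel `ch` is scaled by `√(1 − depth·profile_c(ch))` with 0.1-s
raised-cosine ramps at block edges. Default profiles are contralateral
(left imagery suppresses C4 and half-weight Cz; right suppresses C3 and
Cz; rest suppresses nothing) — a configurable lateralization chosen because
the classifier tests need *some* discriminative signal; profiles can be set
to mimic non-lateralized regimes. Default depth 0.4. Baseline mu amplitude
is 6 µV on C3/Cz/C4 and 2 µV elsewhere, so band power on sensorimotor leads
is mu-dominated and a programmed depth `d` appears as a measured relative
power change of ≈ `−100·d·P_mu/(P_mu+P_noise)` ≈ `−95·d` % — within the
±5-point tolerances used in the tests. Between-session drift multiplies
the depth by 1.15 per step (capped at 0.9), a simple stand-in for subject
learning across weeks.

The montage is the seven named electrodes plus one auxiliary lead labelled
"EX8"; the eighth electrode's identity is configurable rather than guessed.

**What the generator does not emulate** — volume conduction, ocular/EMG
artifacts, non-stationary noise, inter-subject variability, genuinely
non-lateralized ERD, and behavioural feedback effects. Passing tests
therefore show that the implementation is correct and that the pipeline
recovers the signal it is designed for; they do not predict accuracy on
recorded EEG, and the human-subject accuracy tables are explicitly not
reproduction targets (no raw data exist to reproduce them from).

## ERD/ERS maps

Band power is estimated by zero-phase band-pass (3rd-order Butterworth,
8–13 Hz default), squaring, trial-averaging, and binning at 0.1 s;
`RP = (A − R)/R·100` per channel with `R` the mean power in −2…0 s before
task onset. Squared band-passed amplitude binned over ≥ 2 cycles equals the
analytic-envelope power estimate up to ripple, with no Hilbert edge
effects. Epochs destined for ERD analysis are cut with 2 s of pre-onset
context (window −2…+2 s); the archive stores the window offsets. Summary
values quoted in tests average bins in 0.25–1.65 s, clear of the onset and
offset ramps. The estimator is scale-invariant by construction.

## Problem sizes used in the validation suite

Simulation-backed checks run on sessions generated directly at 250 Hz (the
rate the model operates at; the generator's band-limited signal model is
rate-independent, and the 1 kHz → 250 Hz path is exercised separately by
the filtering/decimation tests): the cross-validation checks use the full
900-epoch calibration design; cascade-trend checks use 90-trial calibration
and 60-trial feedback sessions over 5 master seeds; ERD-recovery checks use
100-trial sessions (≥ 100 task windows per condition). Training in these
checks runs up to 40 epochs with patience 10 — past the point where
held-out loss plateaus on these problem sizes.

## IO formats

EDF (16-bit, µV) for continuous recordings — read via `mne`, written by a
minimal writer with 1-s records (the final partial second is zero-padded,
so a read-back recording may be up to 1 s longer; trial structure lives in
the TSV event table, which is exact). Event tables are TSV with 0-based
onsets in seconds and half-open `[start, end)` windows. Epoch archives are
single HDF5 files (`data`, `labels`, per-trial provenance, format-version
attribute); round trips are lossless. Models serialize to a single `.npz`
archive containing the CSP bank, all parameter tensors, shapes, dropout
rates, and training lineage, with a format version.

## Known limitations

- The spatial attention's `d×d` projections make the network heavily
  over-parameterized for single-session data; the layer-group learning
  rates manage, but do not remove, the memorization pressure.
- Eigenvector-based CSP is unstable under near-degenerate eigenvalues;
  sign and tie conventions make results deterministic but small data
  perturbations can still reorder close eigenvalues.
- The EDF writer implements the minimal subset of the format needed here
  (one data-record duration, no annotations, ASCII headers).
- `replay_online` is an offline, frozen-model replay of a feedback session;
  no within-session adaptation is modelled.
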
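# Methods

This note documents the models and procedures implemented in `hvpnet`,
the defaults chosen where a design was genuinely open, and the limits of
what the synthetic benchmark shows.

## Signal model and windowing

A recording is a `T × C` matrix with per-sample gesture label (0 = rest),
per-sample repetition (trial) index and a subject id. Databases are
described by a `DatasetSpec` carrying the electrode count, native and
working sampling rates, class count, rest handling, the fixed
train/test trial split and per-window-length increments; specs for the
five NinaPro sub-databases are built in (DB1: 10 electrodes at 100 Hz,
trials {1,3,4,6,7,8,9} train / {2,5,10} test, rest excluded; DB2–DB4:
12 electrodes at 2 kHz worked at 100 Hz, {1,3,4,6}/{2,5}; DB5: 16
electrodes at 200 Hz, rest kept as a class, 100 ms increment at the
200 ms window; DB4 subjects 4 and 6 excluded as incomplete).

**Downsampling** is plain decimation (keep every k-th sample of signal
and annotation streams). An optional zero-phase Butterworth low-pass
(8th order, 80 % of target Nyquist) can be enabled; it is off by default
because the working definition of the pipeline is decimation, and the
band structure of sEMG above the target Nyquist is not the object of
study here.

**Segmentation** emits `L`-frame windows with stride `S` only inside
maximal runs of constant (label, trial): `⌊(run − L)/S⌋ + 1` windows per
run. Windows therefore never straddle a gesture or trial boundary, which
guarantees a single ground-truth label per window — the accuracy metric
is undefined otherwise. Rest runs are dropped unless the protocol keeps
rest as a class. Window/stride lengths must convert to whole frame
counts at the working rate.

## Views

Three per-channel feature maps turn an `L × C` window into `M_i × C`
feature images (column = electrode), then into depth-major `M_i × C × 1`
tensors (depth = feature index, width = electrode, height = 1). At the
reference setting (200 ms at 100 Hz, so `L = 20`) with the default
wavelet config:

| view | features | default `M_i` |
|------|----------|----------------|
| v1 | DWPT coefficients, all `2^levels` leaves, natural order | 24 |
| v2 | DWT coefficients, deepest approximation then details deepest→shallowest | 21 |
| v3 | `Phin_FS1`: SampEn, AR-cepstral c1–c4, RMS, WL | 7 |

Wavelet defaults: `db1` (Haar), 3 levels, symmetric extension — all
three are config fields, and `M_i` is always derived from the config at
run time, never hard-coded. `Phin_FS1`'s exact composition is likewise
configurable; the default follows the common recommendation of a compact
complexity + time-domain set: sample entropy with `m = 2`,
`r = 0.2·σ(window)`; 4th-order AR-model cepstral coefficients; RMS;
waveform length. Images hold raw feature values — no per-image
rescaling — because every branch batch-normalizes its input; an optional
min–max rescale exists but is off by default.

Numerical edge cases are made finite by construction, since batch
normalization cannot absorb infinities:

- Sample entropy `−ln(A/B)` with zero match counts returns the log of
  the pair-count upper bound `ln(n(n−1)/2)`, `n = L − m`, instead of ∞.
- On a zero-variance window, sample entropy (whose tolerance `0.2·σ`
  degenerates) and the AR model (whose Toeplitz system is singular) are
  reported as 0 within `Phin_FS1`; called directly, `ar_cepstral`
  raises on zero variance.
- AR fitting uses the biased (1/L) autocovariance so Levinson–Durbin
  always sees a positive-definite system. Coefficients follow the
  prediction-error sign convention (`x_t + a_1 x_{t−1} + … = e_t`), and
  cepstra use the standard recursion `c_1 = −a_1`,
  `c_k = −a_k − Σ_{l<k}(1 − l/k) a_l c_{k−l}`.

## Network

Feature maps are `(N, depth, C)` arrays; the singleton height axis of
the `M_i × C × 1` layout is implicit. Consequently the architecture's
3×3 convolutions are realized as 3-tap convolutions along the electrode
axis with zero padding 1 and stride 1 (the height taps of a true 3×3
kernel would only ever multiply zero padding), which preserves the
spatial extent `C` — required for the level-2 concatenation shapes to
work out. Locally connected 1×1 layers are `C` independent depth
transforms (untied weights per electrode). Batch normalization is per
depth channel over batch × electrode for maps and per feature for
vectors; ε = 1e−5, momentum 0.1, **biased** variance throughout so that
adaptation statistics equal directly computed moments. Weights are
He-normal, seeded.

Open points resolved as package defaults (each switchable):

- **Low-level tap point** for level-2 pooling: the output of the *first*
  3×3 convolution (after BN + ReLU) of each view-specific branch. Both
  convolutions produce depth-64 maps, so shape algebra cannot
  disambiguate "bottom"; `tap="second"` selects the other reading.
- **FLVP layer**: concatenation → 1×1 conv → BN + ReLU, consistent with
  the every-layer-BN+ReLU convention; `flvp_bn_relu=False` gives the
  bare linear pooling.
- **Dropout placement**: after the last LC layer and after the FC layer
  of every branch and pooling tail (post-activation); none inside the
  aggregation heads.
- **`vs-l2vp`** (no level-1 branch): the level-2 concatenation holds
  only the per-view low-level maps (depth `n·64`), since no pooled map
  exists to include.
- **Prediction ties** resolve to the lowest class index
  (deterministic).
- In `hvpn-maxpool` / `hvpn-avgpool` only the *level-2* FLVP is replaced
  by an element-wise max/avg — the level-1 inputs have unequal depths,
  so element-wise pooling is not defined there.

The heads emit softmax distributions; the final score is their
element-wise sum (so it totals the head count: 3 for the full model, 2
for single-pooling variants, 1 for `vs-only`).

## Training and evaluation

SGD (optional momentum/weight decay, both 0 by default) with step decay:
rate `lr_init / 10^{#drops ≤ epoch}`; the benchmark-scale protocol is 28
epochs, batch 1000, drops after epochs 16 and 24, dropout 0.65, with
optional pretraining on all subjects' training data at dropout 0.5
followed by per-subject finetuning initialized from the pretrained
weights. **Loss attachment** is open in a multi-head summed-softmax
design; the default sums per-head cross-entropies (each head is
explicitly a classifier), and `loss_mode="summed_score"` instead
maximizes the likelihood of the aggregated score. Shuffling, dropout
masks and initialization all derive from seeded generators, so a run is
bit-reproducible on a fixed-thread CPU.

Intrasubject evaluation trains per subject on the protocol's training
trials and scores the held-out trials; LOSOCV trains each fold on all
windows of the remaining subjects and scores the held-out subject's
protocol *test* trials. Scoring only test trials in LOSOCV keeps the
comparison with and without adaptation on identical data, because the
held-out subject's *training* trials serve as the unlabeled calibration
set for adaptation — calibration data and scored data never overlap.
Both drivers record index-level audit data (trials trained on, fold
memberships) in the result for leakage checks.

**BN-statistics adaptation** clones the trained model, switches every BN
layer into an adaptation mode that normalizes with batch statistics
while accumulating exact activation sums over the calibration passes,
then replaces the running mean/variance with the aggregated moments.
Learnable weights are untouched (verified bitwise in tests); the
procedure is gradient-free, label-free and idempotent for a fixed batch
ordering. The multistream bookkeeping of per-source-subject statistics
is deliberately reduced to its core — target-domain statistic
replacement — which is the part that acts at test time.

## Synthetic data

The generator emulates what the views measure, not muscle physiology:
per electrode, unit-variance Gaussian noise band-passed to 20–45 Hz (at
100 Hz sampling) and amplitude-modulated by a gesture × electrode
activation matrix `a[g, c]`; rest segments carry low-amplitude baseline
noise (0.1). Subject identity enters as fixed log-normal electrode
gains `m[s, c] = exp(σ_shift · z[s, c])` — a multiplicative domain shift
of the kind electrode placement and skin condition produce, and exactly
the distributional mismatch that BN-statistics adaptation targets. The
default activation matrix is `0.5 + contrast · U[0,1)` with fixed draws,
so class separation grows linearly with `contrast` and vanishes at 0.
Labels and 1-based trial indices follow NinaPro conventions; rest
samples carry the upcoming trial's index so rest-keeping protocols can
still split by trial. Everything is a pure function of the seed.

Defaults are the desk-scale study conditions used throughout the tests:
4 subjects, 8 gestures, 6 trials, 10 electrodes at 100 Hz, 2.5 s
contractions, 1 s rests, `σ_shift = 0.3` (the cross-subject study uses
6 gestures, 4 trials, 2 s contractions and `σ_shift = 1.0`).

What passing on this generator shows: the pipeline wiring, the shape
algebra, the optimization loop, the leakage-freedom of the protocols and
the mechanism of BN adaptation all behave as specified, and the model
family can learn amplitude-pattern classes from the constructed views.
What it does not show: performance on real sEMG — the generator has no
motor-unit structure, no gesture-dependent spectral shape, no electrode
shift within a session, no transients at contraction onset, and its
class structure (stationary per-channel energy patterns) is far easier
than real gesture discrimination. Benchmark-scale accuracies therefore
cannot be inferred from these runs.

## Desk-scale problem sizes

The package's own studies (tests and `scripts/acceptance.py`) use a thin
full-architecture network — 16 conv filters, FC 128, aggregation FC 64,
dropout 0.1 — trained 10 epochs at batch 64 with drops after epochs 6
and 8, on 200 ms windows at a 100 ms increment. These sizes were chosen
so a complete study is a few CPU-minutes while every architectural
element (three branches, both pooling levels, three heads, BN
adaptation) stays exercised at full structural fidelity; the
benchmark-scale widths and schedule remain the config defaults of
`HvpnConfig` and `TrainConfig`.

## Known limitations

- The NumPy layer kernel is single-threaded BLAS-bound; benchmark-scale
  training (64 filters, FC 1024, batch 1000, tens of thousands of
  windows) is out of its intended range.
- `restimulus`/`rerepetition` relabeled annotations are supported as a
  loader option; which annotation stream a given published number used
  must be decided by the user.
- Element-wise pooling variants require equal map depths and so exist
  only at level 2; this is a property of the design, not a restriction
  of the implementation.
- Sample entropy is quadratic in the window length; at `L = 20` this is
  negligible, but very long windows would want a KD-tree counter.
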
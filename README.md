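# hvpnet

Multiview convolutional networks with **hierarchical view pooling** for
gesture recognition from multichannel surface electromyography (sEMG).

Sparse-electrode sEMG (10–16 channels, as in the NinaPro benchmark
databases or a Myo armband) carries far less spatial information than
high-density grids, so classifiers for it lean on engineered features.
This package implements a multiview deep-learning pipeline for that
setting, aimed at researchers in myoelectric control and biomedical signal
processing: raw signal windows are turned into several *views* — feature
images of shape `M_i × C` (feature dimension × electrode) — and a CNN
learns both **view-specific** features (one branch per view) and
**view-shared** features (branches fed by pooled multiview feature
spaces), everything exercisable end to end on a built-in synthetic sEMG
generator.

## The model

For a window of `C`-channel sEMG `x`, view construction functions
`v_i = f_i(x)` produce three feature images, each laid out depth-major as
an `M_i × C × 1` tensor (depth, width, height):

- `v1` — discrete wavelet **packet** transform coefficients (DWPTC),
- `v2` — discrete wavelet transform coefficients (DWTC),
- `v3` — `Phin_FS1`, a compact time-domain/complexity set per channel:
  sample entropy, 4 AR-cepstral coefficients, RMS, waveform length.

The network `y = H_a(H_1(v1), …, H_n(vn); θ)` has three parts:

1. **View-specific CNNs** — per view: two 3×3 convolutions (64 filters),
   two locally connected 1×1 layers (64 filters), FC-1024; batch norm +
   ReLU after every layer, dropout on the last LC and the FC layer,
   batch-normalized input. Branches share architecture, not weights.
2. **Hierarchical view-pooling CNNs** — each starts with a
   **feature-level view pooling (FLVP) layer**: depth-concatenation of its
   input maps followed by a 1×1 convolution with 64 filters. Level 1
   pools the raw views (concat depth `M1+M2+M3`); level 2 pools the
   low-level depth-64 maps of all branches plus the level-1 pooled map
   (concat depth `4 × 64 = 256`). Each pooled map feeds a conv/LC/FC
   tail identical in shape to a view-specific branch.
3. **View aggregation** — three streams (concatenated view-specific
   features; level-1 features; level-2 features), each FC-512 → `G`-way
   FC → softmax; the final score is the element-wise **sum of the softmax
   vectors**, and the predicted gesture is its argmax.

Ablation variants are first-class: `hvpn-maxpool` / `hvpn-avgpool`
(element-wise pooling instead of the level-2 FLVP), `vs-l1vp` / `vs-l2vp`
(only one pooling branch), `vs-only` (no pooling branches, single head),
and a two-view configuration (`v1`, `v2` only).

Training follows the benchmark protocol — SGD, learning rate 0.1 divided
by 10 after epochs 16 and 24 (28 epochs), batch 1000, dropout 0.65 (0.5
during optional pretraining on pooled data) — with every quantity
configurable for desk-scale runs. Evaluation is the per-subject accuracy
`100 × correct / total`, averaged over subjects (intrasubject, fixed
trial splits) or over leave-one-subject-out folds (LOSOCV), plus
per-trial majority voting. For cross-subject use, AdaBN-style adaptation
re-estimates every batch-normalization layer's running statistics from
unlabeled calibration data of the target subject without touching any
learned weight.

## Worked example

```python
from hvpnet import run_experiment

config = {
    "experiment": "intrasubject",
    "seed": 1,
    "synthetic": {"n_subjects": 2, "n_gestures": 4, "n_trials": 6,
                  "channels": 10, "trial_duration": 2.0},
    "windows": {"window_ms": 200, "increment_ms": 100},
    "views": {"ids": [1, 2, 3]},
    "model": {"variant": "hvpn", "conv_filters": 16, "fc_units": 128,
              "agg_units": 64, "dropout_rate": 0.1},
    "train": {"epochs": 10, "batch_size": 64, "lr_init": 0.1,
              "lr_drops": [6, 8]},
}
manifest, metrics = run_experiment(config)
for sid, acc in metrics["per_unit_accuracy"].items():
    print(f"subject {sid}: window accuracy {acc:.1f}%")
print(f"mean window accuracy: {metrics['mean_accuracy']:.1f}%")
print(f"trial majority-voting accuracy: {metrics['voting_mean_accuracy']:.1f}%")
```

prints

```
subject 0: window accuracy 92.8%
subject 1: window accuracy 87.5%
mean window accuracy: 90.1%
trial majority-voting accuracy: 100.0%
```

Two synthetic subjects each perform 4 gestures 6 times; trials
{1,3,4,6} train a thin full-architecture model per subject and trials
{2,5} are scored. Each 200 ms window is classified on its own
(~90 % here), and majority voting over the windows of a whole trial
fixes the remaining scattered window errors (100 %).

The same pipeline is scriptable from the shell:

```bash
hvpn simulate --out scratch/sim --subjects 4
hvpn eval-intra --seed 1            # JSON metrics on stdout
hvpn eval-losocv --adapt --seed 1
hvpn ablate --variants hvpn,vs-only
```

Real NinaPro matrix files (fields `emg`, `stimulus`/`restimulus`,
`repetition`) load through `hvpnet.load_ninapro_matrix` with the
per-database protocol specs from `hvpnet.ninapro_spec("db1")` …
`("db5")`; nothing in the package downloads data.

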
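"""Training protocol, evaluation schemes and BN-statistics domain adaptation.

The protocol mirrors common practice for CNN gesture recognizers on the
NinaPro benchmarks: SGD with a step learning-rate decay (0.1, divided by
10 after epochs 16 and 24, over 28 epochs at the benchmark scale), batch
training with per-head cross-entropy summed over all classifier heads, an
optional pretrain-on-everyone / finetune-per-subject stage (dropout 0.5
while pretraining, 0.65 afterwards), window accuracy as the metric, and
per-trial majority voting.  Intersubject transfer uses leave-one-subject-
out cross-validation (LOSOCV) with AdaBN-style adaptation: the trained
network's batch-normalization statistics are re-estimated from unlabeled
calibration data of the target subject, with every learnable weight left
untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import HvpnConfig, HvpnModel, build_model, clone_model, predict
from .nn import BatchNorm, Dropout, SGD, add_n, nll_of_summed_scores, \
    softmax_cross_entropy
from .signals import DatasetSpec, EmgRecording, WindowSet, downsample, \
    segment_windows, split_by_trial
from .views import ALL_VIEWS, MultiViewBatch, ViewConfig, construct_views

__all__ = [
    "TrainConfig", "EvalResult", "FeaturizedSet", "lr_schedule", "train",
    "pretrain_then_finetune", "accuracy", "majority_vote", "featurize",
    "intrasubject_eval", "losocv_eval", "adabn_adapt", "set_dropout",
]


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule and batching.

    ``dropout`` overrides the model's dropout rate when set (the protocol
    uses 0.5 for pretraining and 0.65 for subject-specific training).
    ``loss_mode``: ``per_head_sum`` attaches a cross-entropy loss to every
    classifier head and sums them; ``summed_score`` trains the likelihood
    of the aggregated (summed-softmax) score directly.
    """

    epochs: int = 28
    batch_size: int = 1000
    lr_init: float = 0.1
    lr_drops: tuple[int, ...] = (16, 24)
    dropout: float | None = None
    momentum: float = 0.0
    weight_decay: float = 0.0
    seed: int = 0
    loss_mode: str = "per_head_sum"

    def __post_init__(self) -> None:
        if list(self.lr_drops) != sorted(set(self.lr_drops)):
            raise ValueError("lr_drops must be strictly increasing")
        if self.lr_drops and self.lr_drops[-1] >= self.epochs:
            raise ValueError("lr_drops must lie before the last epoch")
        if self.loss_mode not in ("per_head_sum", "summed_score"):
            raise ValueError("loss_mode must be per_head_sum or summed_score")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: the initial rate divided by 10 at each configured drop."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if epoch >= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside the {cfg.epochs}-epoch run")
    drops = sum(1 for d in cfg.lr_drops if epoch >= d)
    return cfg.lr_init / 10.0 ** drops


def set_dropout(model: HvpnModel, rate: float) -> None:
    """Set every dropout layer of a model to ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    for m in model.modules():
        if isinstance(m, Dropout):
            m.p = rate


def _view_arrays(views) -> list[np.ndarray]:
    if isinstance(views, MultiViewBatch):
        return views.arrays
    return [np.asarray(v, dtype=np.float64) for v in views]


def train(model: HvpnModel, views, labels: np.ndarray,
          cfg: TrainConfig = TrainConfig()) -> list[float]:
    """SGD-train a model in place; returns the per-epoch mean loss trace.

    Deterministic for a fixed seed: shuffling, dropout masks and batch
    order all derive from one seeded generator.
    """
    arrays = _view_arrays(views)
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if arrays[0].shape[0] != n:
        raise ValueError("views and labels disagree on the sample count")
    if labels.min() < 0 or labels.max() >= model.cfg.num_classes:
        raise ValueError("labels must lie in [0, num_classes)")
    if cfg.dropout is not None:
        set_dropout(model, cfg.dropout)

    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr_init, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    model.train(True)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            batch = [a[idx] for a in arrays]
            out = model.forward(batch, rng=rng)
            if cfg.loss_mode == "per_head_sum":
                loss = add_n([softmax_cross_entropy(z, labels[idx])
                              for z in out.head_logits])
            else:
                loss = nll_of_summed_scores(out.final_scores, labels[idx],
                                            model.n_heads)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    model.eval()
    return trace


def pretrain_then_finetune(pretrain_data: tuple, per_subject: dict,
                           model_cfg: HvpnConfig,
                           pretrain_cfg: TrainConfig,
                           finetune_cfg: TrainConfig,
                           init_seed: int = 0):
    """Train a shared model on pooled data, then finetune one copy per subject.

    ``pretrain_data`` is ``(views, labels)`` pooled over all training
    subjects; ``per_subject`` maps subject id to that subject's
    ``(views, labels)``.  Each subject model starts from the pretrained
    weights exactly.  Returns ``(pretrained_model, {sid: model})``.
    """
    if pretrain_cfg.dropout is None:
        pretrain_cfg = dataclasses.replace(pretrain_cfg, dropout=0.5)
    if finetune_cfg.dropout is None:
        finetune_cfg = dataclasses.replace(finetune_cfg, dropout=0.65)
    pre = build_model(model_cfg, seed=init_seed)
    train(pre, *pretrain_data, pretrain_cfg)
    out: dict[int, HvpnModel] = {}
    for sid, (views, labels) in per_subject.items():
        m = clone_model(pre)
        train(m, views, labels, finetune_cfg)
        out[sid] = m
    return pre, out


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Percentage of correct classifications, ``100 * correct / total``."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(100.0 * np.mean(predictions == labels))


def majority_vote(window_predictions: np.ndarray) -> int:
    """Most frequent predicted class in a trial; ties go to the lowest class."""
    preds = np.asarray(window_predictions, dtype=np.int64)
    if preds.size == 0:
        raise ValueError("cannot vote on an empty prediction list")
    return int(np.bincount(preds).argmax())


@dataclass
class EvalResult:
    """Per-subject (or per-fold) accuracies in percent, plus their mean."""

    per_unit_accuracy: dict[int, float]
    mean_accuracy: float = field(init=False)
    voting_per_unit: dict[int, float] | None = None
    voting_mean: float | None = field(init=False, default=None)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = list(self.per_unit_accuracy.values())
        if not vals:
            raise ValueError("no evaluation units")
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError("accuracies must lie in [0, 100]")
        self.mean_accuracy = float(np.mean(vals))
        if self.voting_per_unit:
            self.voting_mean = float(np.mean(list(self.voting_per_unit.values())))


@dataclass
class FeaturizedSet:
    """View tensors plus aligned labels and bookkeeping for one window set."""

    views: MultiViewBatch
    labels: np.ndarray          # class indices in [0, G)
    gesture_labels: np.ndarray  # original gesture ids
    trial_ids: np.ndarray
    subject_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concatenate(parts: list["FeaturizedSet"]) -> "FeaturizedSet":
        return FeaturizedSet(
            MultiViewBatch([np.concatenate([p.views.arrays[j] for p in parts])
                            for j in range(len(parts[0].views.arrays))],
                           parts[0].views.view_ids),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.gesture_labels for p in parts]),
            np.concatenate([p.trial_ids for p in parts]),
            np.concatenate([p.subject_ids for p in parts]))


def _encode(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, labels)
    if (idx >= len(classes)).any() or (classes[idx] != labels).any():
        raise ValueError("window label outside the class set")
    return idx


def featurize(ws: WindowSet, classes: np.ndarray,
              view_ids: tuple[int, ...] = ALL_VIEWS,
              view_cfg: ViewConfig = ViewConfig()) -> FeaturizedSet:
    """Construct views for a window set and encode labels as class indices."""
    return FeaturizedSet(construct_views(ws, view_ids, view_cfg),
                         _encode(ws.labels, classes), ws.labels.copy(),
                         ws.trial_ids.copy(), ws.subject_ids.copy())


def _segment_subject(rec: EmgRecording, spec: DatasetSpec, window_ms: int,
                     increment_ms: int | None) -> WindowSet:
    if rec.sampling_rate != spec.working_rate:
        rec = downsample(rec, spec.working_rate)
    if increment_ms is None:
        increment_ms = spec.increment_for(window_ms)
    return segment_windows(rec, window_ms, increment_ms,
                           drop_rest=not spec.include_rest)


def _class_set(recs: list[EmgRecording], spec: DatasetSpec) -> np.ndarray:
    labels = np.unique(np.concatenate([r.gesture_label for r in recs]))
    if not spec.include_rest:
        labels = labels[labels != 0]
    return labels


def _voting_accuracy(preds: np.ndarray, fset: FeaturizedSet) -> float:
    keys = np.stack([fset.gesture_labels, fset.trial_ids], axis=1)
    trial_true, trial_pred = [], []
    for key in np.unique(keys, axis=0):
        mask = (keys == key).all(axis=1)
        trial_pred.append(majority_vote(preds[mask]))
        trial_true.append(fset.labels[mask][0])
    return accuracy(np.asarray(trial_pred), np.asarray(trial_true))


def _model_cfg(base: dict, view_dims: tuple[int, ...], channels: int,
               num_classes: int) -> HvpnConfig:
    return HvpnConfig(view_dims=view_dims, channels=channels,
                      num_classes=num_classes, **base)


def intrasubject_eval(dataset: list[EmgRecording], spec: DatasetSpec,
                      train_cfg: TrainConfig = TrainConfig(),
                      model_kwargs: dict | None = None,
                      view_ids: tuple[int, ...] = ALL_VIEWS,
                      view_cfg: ViewConfig = ViewConfig(),
                      window_ms: int = 200, increment_ms: int | None = None,
                      pretrain_cfg: TrainConfig | None = None,
                      vote: bool = True) -> EvalResult:
    """Within-subject evaluation on the protocol's trial split.

    For every subject roughly 2/3 of the trials train a subject-specific
    model and the held-out trials are scored; the reported accuracy is the
    mean over subjects.  With ``pretrain_cfg`` set, a model pretrained on
    all subjects' training trials initializes each subject's model.
    Per-trial majority-voting accuracy is reported alongside.
    """
    dataset = [r for r in dataset if r.subject_id not in spec.excluded_subjects]
    classes = _class_set(dataset, spec)
    model_kwargs = dict(model_kwargs or {})

    subject_sets: dict[int, tuple[FeaturizedSet, FeaturizedSet]] = {}
    for rec in dataset:
        ws = _segment_subject(rec, spec, window_ms, increment_ms)
        tr, te = split_by_trial(ws, spec)
        if len(te) == 0:
            raise ValueError(f"subject {rec.subject_id} has an empty test set")
        subject_sets[rec.subject_id] = (
            featurize(tr, classes, view_ids, view_cfg),
            featurize(te, classes, view_ids, view_cfg))

    any_train = next(iter(subject_sets.values()))[0]
    cfg = _model_cfg(model_kwargs, any_train.views.view_dims,
                     any_train.views.arrays[0].shape[2], len(classes))

    if pretrain_cfg is not None:
        pooled = FeaturizedSet.concatenate(
            [tr for tr, _ in subject_sets.values()])
        _, models = pretrain_then_finetune(
            (pooled.views, pooled.labels),
            {sid: (tr.views, tr.labels)
             for sid, (tr, _) in subject_sets.items()},
            cfg, pretrain_cfg, train_cfg, init_seed=train_cfg.seed)
    else:
        models = {}
        for i, (sid, (tr, _)) in enumerate(sorted(subject_sets.items())):
            m = build_model(cfg, seed=train_cfg.seed + i)
            train(m, tr.views, tr.labels, train_cfg)
            models[sid] = m

    per_acc, per_vote = {}, {}
    for sid, (_, te) in sorted(subject_sets.items()):
        preds = predict(models[sid], te.views.arrays)
        per_acc[sid] = accuracy(preds, te.labels)
        if vote:
            per_vote[sid] = _voting_accuracy(preds, te)
    audit = {  # which trials actually fed gradients / scoring, per subject
        "train_trial_ids": {sid: sorted(np.unique(tr.trial_ids).tolist())
                            for sid, (tr, _) in subject_sets.items()},
        "test_trial_ids": {sid: sorted(np.unique(te.trial_ids).tolist())
                           for sid, (_, te) in subject_sets.items()},
        "n_test_windows": int(sum(len(te) for _, te in subject_sets.values())),
    }
    return EvalResult(per_acc, voting_per_unit=per_vote or None, extras=audit)


def adabn_adapt(model: HvpnModel, calibration_views,
                batch_size: int = 256) -> HvpnModel:
    """Re-estimate every BN layer's running statistics from calibration data.

    Returns an adapted copy: learnable weights are bitwise identical to
    the input model's, and each BN layer's running mean/variance become
    the exact aggregated moments of its calibration-pass activations
    (batch statistics normalize each pass, as in training).  No gradients
    are computed; labels are not needed.
    """
    arrays = _view_arrays(calibration_views)
    n = arrays[0].shape[0]
    if n == 0:
        raise ValueError("empty calibration set")
    adapted = clone_model(model)
    adapted.eval()  # dropout off; BN mode is driven by the adapt flag
    bns = [m for m in adapted.modules() if isinstance(m, BatchNorm)]
    for bn in bns:
        bn.begin_adapt()
    for lo in range(0, n, batch_size):
        adapted.forward([a[lo:lo + batch_size] for a in arrays])
    for bn in bns:
        bn.finish_adapt()
    return adapted


def losocv_eval(dataset: list[EmgRecording], spec: DatasetSpec,
                train_cfg: TrainConfig = TrainConfig(),
                model_kwargs: dict | None = None,
                view_ids: tuple[int, ...] = ALL_VIEWS,
                view_cfg: ViewConfig = ViewConfig(),
                window_ms: int = 200, increment_ms: int | None = None,
                adaptation: bool = False) -> EvalResult:
    """Leave-one-subject-out cross-validation, optionally with adaptation.

    Each fold trains on every window of the remaining subjects and scores
    the held-out subject's protocol test trials.  With ``adaptation`` the
    held-out subject's training-trial windows serve as unlabeled
    calibration data for BN-statistics adaptation before scoring (the test
    trials are never touched); the unadapted fold accuracies are kept in
    ``extras['unadapted_accuracy']`` for comparison.
    """
    dataset = [r for r in dataset if r.subject_id not in spec.excluded_subjects]
    if len(dataset) < 2:
        raise ValueError("LOSOCV needs at least 2 subjects")
    classes = _class_set(dataset, spec)
    model_kwargs = dict(model_kwargs or {})

    full, calib, test = {}, {}, {}
    for rec in dataset:
        ws = _segment_subject(rec, spec, window_ms, increment_ms)
        tr, te = split_by_trial(ws, spec)
        full[rec.subject_id] = featurize(ws, classes, view_ids, view_cfg)
        calib[rec.subject_id] = featurize(tr, classes, view_ids, view_cfg)
        test[rec.subject_id] = featurize(te, classes, view_ids, view_cfg)

    sids = sorted(full)
    cfg = _model_cfg(model_kwargs, full[sids[0]].views.view_dims,
                     full[sids[0]].views.arrays[0].shape[2], len(classes))

    per_acc, per_unadapted = {}, {}
    fold_train_subjects: dict[int, list[int]] = {}
    for i, held_out in enumerate(sids):
        pooled = FeaturizedSet.concatenate(
            [full[s] for s in sids if s != held_out])
        fold_train_subjects[held_out] = sorted(
            np.unique(pooled.subject_ids).tolist())
        m = build_model(cfg, seed=train_cfg.seed + i)
        train(m, pooled.views, pooled.labels, train_cfg)
        te = test[held_out]
        preds = predict(m, te.views.arrays)
        base_acc = accuracy(preds, te.labels)
        if adaptation:
            adapted = adabn_adapt(m, calib[held_out].views.arrays)
            preds = predict(adapted, te.views.arrays)
            per_unadapted[held_out] = base_acc
            per_acc[held_out] = accuracy(preds, te.labels)
        else:
            per_acc[held_out] = base_acc
    extras: dict = {"fold_train_subjects": fold_train_subjects,
                    "n_test_windows": int(sum(len(test[s]) for s in sids))}
    if adaptation:
        extras["unadapted_accuracy"] = per_unadapted
    return EvalResult(per_acc, extras=extras)
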
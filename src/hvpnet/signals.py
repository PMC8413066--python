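"""Multichannel sEMG data model, loading, windowing and trial-based splits.

A recording is the raw material of a myoelectric gesture-recognition
experiment: a ``T x C`` signal matrix from ``C`` sparsely placed surface
electrodes, with a per-sample gesture label (0 = rest), a per-sample
repetition (trial) index and a subject id.  NinaPro-style matrix container
files (``emg`` / ``stimulus`` or ``restimulus`` / ``repetition`` fields) are
supported through :func:`load_ninapro_matrix`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.io
import scipy.signal

__all__ = [
    "EmgRecording",
    "DatasetSpec",
    "WindowSet",
    "ninapro_spec",
    "downsample",
    "segment_windows",
    "split_by_trial",
    "load_ninapro_matrix",
    "save_ninapro_matrix",
]


@dataclass
class EmgRecording:
    """A labelled multichannel sEMG recording for one subject.

    Parameters
    ----------
    signal:
        ``(T, C)`` float array, arbitrary amplitude units.
    sampling_rate:
        Sampling rate in Hz.
    gesture_label:
        ``(T,)`` non-negative integer labels, 0 meaning rest.
    repetition:
        ``(T,)`` trial indices (1-based for gesture segments).
    subject_id:
        Integer subject identifier.
    """

    signal: np.ndarray
    sampling_rate: float
    gesture_label: np.ndarray
    repetition: np.ndarray
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[1] < 1:
            raise ValueError("signal must be a (T, C) matrix with C >= 1")
        self.gesture_label = np.asarray(self.gesture_label, dtype=np.int64)
        self.repetition = np.asarray(self.repetition, dtype=np.int64)
        T = self.signal.shape[0]
        if self.gesture_label.shape != (T,) or self.repetition.shape != (T,):
            raise ValueError("label and repetition streams must have length T")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if (self.gesture_label < 0).any():
            raise ValueError("gesture labels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def channels(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class DatasetSpec:
    """Static description of one evaluation database and its protocol.

    ``train_trials`` / ``test_trials`` hold the repetition indices used for
    the intrasubject split (roughly a 2/3 : 1/3 partition of the trials).
    ``window_increment_ms`` maps window length (ms) to the sliding-window
    increment (ms) used with it.
    """

    name: str
    channels: int
    native_rate: float
    working_rate: float
    num_classes: int
    include_rest: bool
    train_trials: frozenset[int]
    test_trials: frozenset[int]
    window_increment_ms: Mapping[int, int] = field(default_factory=dict)
    excluded_subjects: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.train_trials & self.test_trials:
            raise ValueError("train and test trial sets must be disjoint")
        if self.num_classes < 2:
            raise ValueError("need at least 2 gesture classes")
        ratio = self.native_rate / self.working_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("working_rate must divide native_rate")

    def increment_for(self, window_ms: int, default: int = 10) -> int:
        return int(self.window_increment_ms.get(window_ms, default))


#: Per-database protocol constants: intact/amputee NinaPro sub-databases.
#: Rest is kept as a class only for the DB5-style protocol (41 gestures
#: including rest); DB1-style protocols exclude it.  The 100 ms increment
#: applies only to DB5 at a 200 ms window; all other settings use 10 ms.
_NINAPRO_SPECS = {
    "db1": dict(channels=10, native_rate=100.0, working_rate=100.0,
                num_classes=52, include_rest=False,
                train_trials=frozenset({1, 3, 4, 6, 7, 8, 9}),
                test_trials=frozenset({2, 5, 10})),
    "db2": dict(channels=12, native_rate=2000.0, working_rate=100.0,
                num_classes=49, include_rest=False,
                train_trials=frozenset({1, 3, 4, 6}),
                test_trials=frozenset({2, 5})),
    "db3": dict(channels=12, native_rate=2000.0, working_rate=100.0,
                num_classes=49, include_rest=False,
                train_trials=frozenset({1, 3, 4, 6}),
                test_trials=frozenset({2, 5})),
    "db4": dict(channels=12, native_rate=2000.0, working_rate=100.0,
                num_classes=52, include_rest=False,
                train_trials=frozenset({1, 3, 4, 6}),
                test_trials=frozenset({2, 5}),
                excluded_subjects=frozenset({4, 6})),
    "db5": dict(channels=16, native_rate=200.0, working_rate=200.0,
                num_classes=41, include_rest=True,
                train_trials=frozenset({1, 3, 4, 6}),
                test_trials=frozenset({2, 5}),
                window_increment_ms={200: 100}),
}


def ninapro_spec(name: str) -> DatasetSpec:
    """Return the protocol spec for one of the NinaPro sub-databases (db1-db5)."""
    key = name.lower()
    if key not in _NINAPRO_SPECS:
        raise KeyError(f"unknown dataset spec {name!r}; choose from {sorted(_NINAPRO_SPECS)}")
    return DatasetSpec(name=key, **_NINAPRO_SPECS[key])


@dataclass
class WindowSet:
    """Segmented sliding windows ready for view construction.

    ``windows`` has shape ``(n, L, C)``; every window lies entirely inside one
    contiguous run of constant (gesture label, repetition).
    """

    windows: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    subject_ids: np.ndarray
    window_ms: int
    increment_ms: int

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        n = self.windows.shape[0]
        for name in ("labels", "trial_ids", "subject_ids"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per window")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[mask], self.labels[mask],
                         self.trial_ids[mask], self.subject_ids[mask],
                         self.window_ms, self.increment_ms)

    @staticmethod
    def concatenate(parts: Iterable["WindowSet"]) -> "WindowSet":
        parts = list(parts)
        if not parts:
            raise ValueError("no window sets to concatenate")
        w0 = parts[0]
        return WindowSet(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.trial_ids for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            w0.window_ms, w0.increment_ms)


def downsample(rec: EmgRecording, target_rate: float,
               antialias: bool = False) -> EmgRecording:
    """Decimate a recording to ``target_rate`` by keeping every k-th sample.

    The label and repetition streams are decimated with the same stride so
    they stay aligned.  ``antialias`` optionally low-pass filters the signal
    (8th-order zero-phase Butterworth at 80 % of the target Nyquist) before
    decimation; plain decimation is the default.
    """
    ratio = rec.sampling_rate / target_rate
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target rate {target_rate} Hz is not an integer divisor of "
            f"{rec.sampling_rate} Hz")
    if k == 1:
        return dataclasses.replace(rec)
    sig = rec.signal
    if antialias:
        sos = scipy.signal.butter(8, 0.8 * (target_rate / 2),
                                  fs=rec.sampling_rate, output="sos")
        sig = scipy.signal.sosfiltfilt(sos, sig, axis=0)
    return EmgRecording(sig[::k], target_rate, rec.gesture_label[::k],
                        rec.repetition[::k], rec.subject_id)


def _runs(label: np.ndarray, repetition: np.ndarray):
    """Yield (start, stop, label, rep) for maximal constant (label, rep) runs."""
    T = label.shape[0]
    if T == 0:
        return
    change = np.flatnonzero((np.diff(label) != 0) | (np.diff(repetition) != 0))
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [T]])
    for s, e in zip(starts, stops):
        yield int(s), int(e), int(label[s]), int(repetition[s])


def segment_windows(rec: EmgRecording, window_ms: int, increment_ms: int,
                    drop_rest: bool = True) -> WindowSet:
    """Sliding-window segmentation that never straddles a label or trial edge.

    Within each maximal run of constant (label, repetition) the function
    emits ``floor((run_len - L) / S) + 1`` windows of ``L`` frames with
    stride ``S`` frames (none if the run is shorter than ``L``).  Each window
    inherits the run's gesture label and trial id, which guarantees a single
    ground-truth label per window.
    """
    fs = rec.sampling_rate
    L = window_ms * fs / 1000.0
    S = increment_ms * fs / 1000.0
    if abs(L - round(L)) > 1e-9 or abs(S - round(S)) > 1e-9:
        raise ValueError("window and increment must be whole frame counts "
                         f"at {fs} Hz")
    L, S = int(round(L)), int(round(S))
    if L < 1 or S < 1:
        raise ValueError("window and increment must be at least one frame")

    starts, labels, trials = [], [], []
    for s, e, lab, rep in _runs(rec.gesture_label, rec.repetition):
        if drop_rest and lab == 0:
            continue
        n = (e - s - L) // S + 1
        if n <= 0:
            continue
        run_starts = s + S * np.arange(n)
        starts.append(run_starts)
        labels.append(np.full(n, lab))
        trials.append(np.full(n, rep))

    if starts:
        starts = np.concatenate(starts)
        idx = starts[:, None] + np.arange(L)[None, :]
        windows = rec.signal[idx]  # (n, L, C)
        labels = np.concatenate(labels)
        trials = np.concatenate(trials)
    else:
        windows = np.empty((0, L, rec.channels))
        labels = np.empty(0, dtype=np.int64)
        trials = np.empty(0, dtype=np.int64)
    subj = np.full(len(labels), rec.subject_id, dtype=np.int64)
    return WindowSet(windows, labels, trials, subj, window_ms, increment_ms)


def split_by_trial(ws: WindowSet, spec: DatasetSpec) -> tuple[WindowSet, WindowSet]:
    """Partition a window set into train/test by repetition index."""
    known = spec.train_trials | spec.test_trials
    unknown = {int(t) for t in np.unique(ws.trial_ids)} - known
    if unknown:
        raise ValueError(f"trial id(s) {sorted(unknown)} not assigned to train "
                         f"or test in spec {spec.name!r}")
    train_mask = np.isin(ws.trial_ids, sorted(spec.train_trials))
    return ws.subset(train_mask), ws.subset(~train_mask)


def load_ninapro_matrix(path: str | Path, spec: DatasetSpec,
                        label_field: str = "stimulus",
                        subject_id: int = 0) -> EmgRecording:
    """Load a NinaPro-style matrix container file.

    ``label_field`` selects the annotation stream: ``"stimulus"`` (as
    provided) or ``"restimulus"`` (movement-onset relabelled); with
    ``"restimulus"`` the ``rerepetition`` stream is used when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    mat = scipy.io.loadmat(path)
    if "emg" not in mat:
        raise ValueError(f"{path} has no 'emg' field")
    if label_field not in mat:
        raise ValueError(f"{path} has no {label_field!r} field")
    rep_field = "rerepetition" if (label_field == "restimulus"
                                   and "rerepetition" in mat) else "repetition"
    if rep_field not in mat:
        raise ValueError(f"{path} has no {rep_field!r} field")
    emg = np.asarray(mat["emg"], dtype=np.float64)
    if emg.shape[1] != spec.channels:
        raise ValueError(f"{path} has {emg.shape[1]} channels, spec "
                         f"{spec.name!r} expects {spec.channels}")
    label = np.asarray(mat[label_field]).reshape(-1)
    rep = np.asarray(mat[rep_field]).reshape(-1)
    return EmgRecording(emg, spec.native_rate, label, rep, subject_id)


def save_ninapro_matrix(path: str | Path, rec: EmgRecording) -> None:
    """Write a recording as a NinaPro-style matrix container file."""
    scipy.io.savemat(str(path), {
        "emg": rec.signal,
        "stimulus": rec.gesture_label[:, None].astype(np.float64),
        "repetition": rec.repetition[:, None].astype(np.float64),
        "subject": np.array([[rec.subject_id]], dtype=np.float64),
    })
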
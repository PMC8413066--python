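"""Synthetic multi-subject, multi-trial multichannel sEMG generator.

Surface EMG during a steady contraction is well approximated, for the
purposes of the features used here (per-channel energy, waveform
complexity, wavelet subband content), by band-limited Gaussian noise whose
amplitude depends on which muscles are active.  The generator therefore
synthesizes, for subject ``s``, gesture ``g`` and electrode ``c``,

    signal = a[g, c] * m[s, c] * n(t)      during gesture segments,
    signal = a_rest * n(t)                 during rest,

where ``n(t)`` is unit-variance Gaussian noise band-passed to
``noise_band`` (20-45 Hz at a 100 Hz sampling rate by default), ``a`` is a
gesture-by-electrode activation matrix, and ``m[s, c] =
exp(subject_shift_sd * z[s, c])`` is a fixed per-subject multiplicative
electrode gain (log-normal) that creates the cross-subject domain shift
that BN-statistics adaptation targets.  Trials are laid out as
rest / gesture / rest ... sequences with per-sample labels (0 = rest) and
1-based repetition indices, mirroring NinaPro annotation conventions.
Everything is a pure function of the seed.

Defaults follow the desk-scale study conditions used throughout the test
suite: 4 subjects, 8 gestures, 6 trials per gesture, 10 electrodes at
100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signals import EmgRecording

__all__ = ["SyntheticSpec", "generate", "default_activation_matrix",
           "protocol_spec"]


def default_activation_matrix(G: int, C: int, contrast: float = 1.0,
                              seed: int = 0) -> np.ndarray:
    """Gesture-by-electrode activation amplitudes with tunable separation.

    Rows are ``0.5 + contrast * u[g, c]`` with fixed uniform ``u`` drawn
    from ``seed``: at ``contrast = 0`` all gestures collapse onto the same
    activation pattern, and the pairwise row separation grows linearly
    with ``contrast``.
    """
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    rng = np.random.default_rng(seed)
    u = rng.random((G, C))
    return 0.5 + contrast * u


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_subjects: int = 4
    n_gestures: int = 8
    n_trials: int = 6
    channels: int = 10
    sampling_rate: float = 100.0
    trial_duration: float = 2.5
    rest_duration: float = 1.0
    activation_matrix: np.ndarray | None = None
    activation_contrast: float = 1.0
    subject_shift_sd: float = 0.3
    noise_band: tuple[float, float] = (20.0, 45.0)
    rest_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gestures < 2:
            raise ValueError("need at least 2 gesture classes")
        low, high = self.noise_band
        if not 0 < low < high:
            raise ValueError("noise_band must satisfy 0 < low < high")
        if high >= self.sampling_rate / 2:
            raise ValueError("noise_band upper edge must lie below Nyquist")
        if self.activation_matrix is not None:
            a = np.asarray(self.activation_matrix, dtype=np.float64)
            if a.shape != (self.n_gestures, self.channels):
                raise ValueError("activation_matrix must be (G, C)")
            if (a < 0).any():
                raise ValueError("activation amplitudes must be non-negative")
            object.__setattr__(self, "activation_matrix", a)

    def resolved_activation(self) -> np.ndarray:
        if self.activation_matrix is not None:
            return self.activation_matrix
        return default_activation_matrix(self.n_gestures, self.channels,
                                         self.activation_contrast, self.seed)


def protocol_spec(spec: SyntheticSpec) -> "DatasetSpec":
    """Evaluation protocol for a synthetic dataset.

    Roughly 2/3 of the trials train, the rest test: every third trial
    starting from the 2nd is held out (for 6 trials this is the
    {1,3,4,6} / {2,5} split used by the multi-trial benchmarks).
    """
    from .signals import DatasetSpec
    trials = set(range(1, spec.n_trials + 1))
    test = {t for t in trials if t % 3 == 2}
    return DatasetSpec(
        name="synthetic", channels=spec.channels,
        native_rate=spec.sampling_rate, working_rate=spec.sampling_rate,
        num_classes=spec.n_gestures, include_rest=False,
        train_trials=frozenset(trials - test), test_trials=frozenset(test))


def _band_noise(rng: np.random.Generator, n: int, channels: int,
                band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed per channel."""
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, channels))
    x = scipy.signal.sosfiltfilt(sos, white, axis=0)
    return x / x.std(axis=0, keepdims=True)


def generate(spec: SyntheticSpec) -> list[EmgRecording]:
    """Generate one labelled recording per subject, fully seeded.

    Gesture blocks are interleaved NinaPro-style: for each gesture in turn,
    a rest block then one trial of the gesture, cycling through all
    gestures ``n_trials`` times.  Rest samples carry label 0 and the
    repetition index of the following gesture block (so protocols that
    keep rest as a class can still split rest windows by trial).
    """
    fs = spec.sampling_rate
    act = spec.resolved_activation()
    n_gest = int(round(spec.trial_duration * fs))
    n_rest = int(round(spec.rest_duration * fs))
    if n_gest < 1:
        raise ValueError("trial_duration too short for the sampling rate")

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    recordings = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(seeds[s])
        gains = np.exp(spec.subject_shift_sd
                       * rng.standard_normal(spec.channels))
        blocks_sig, blocks_lab, blocks_rep = [], [], []
        for trial in range(1, spec.n_trials + 1):
            for g in range(1, spec.n_gestures + 1):
                rest = spec.rest_amplitude * _band_noise(
                    rng, n_rest, spec.channels, spec.noise_band, fs)
                blocks_sig.append(rest)
                blocks_lab.append(np.zeros(n_rest, dtype=np.int64))
                blocks_rep.append(np.full(n_rest, trial, dtype=np.int64))
                burst = _band_noise(rng, n_gest, spec.channels,
                                    spec.noise_band, fs)
                blocks_sig.append(burst * (act[g - 1] * gains)[None, :])
                blocks_lab.append(np.full(n_gest, g, dtype=np.int64))
                blocks_rep.append(np.full(n_gest, trial, dtype=np.int64))
        recordings.append(EmgRecording(
            np.concatenate(blocks_sig), fs,
            np.concatenate(blocks_lab), np.concatenate(blocks_rep),
            subject_id=s))
    return recordings
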
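"""Run configuration, schema validation and experiment manifests.

A run is described by a nested mapping (usually a YAML file) with the
sections below; unknown keys are rejected with an error naming them, so a
config snapshot plus the seed is sufficient to repeat a run.

    experiment: intrasubject | losocv
    seed: 0
    outdir: null            # directory for metrics/manifest JSON (optional)
    synthetic: {...}        # SyntheticSpec fields
    windows: {window_ms: 200, increment_ms: 100}
    views: {ids: [1, 2, 3], wavelet: {family: db1, levels: 3,
            extension_mode: symmetric}, minmax_scale: false}
    model: {variant: hvpn, conv_filters: 16, fc_units: 128, agg_units: 64,
            dropout_rate: 0.1, tap: first}
    train: {epochs: 10, batch_size: 64, lr_init: 0.1, lr_drops: [6, 8],
            momentum: 0.0, weight_decay: 0.0, loss_mode: per_head_sum}
    pretrain: {enabled: false, epochs: 5, dropout: 0.5}
    adaptation: {enabled: false}

The defaults above are the desk-scale settings (narrow network, sparse
windowing) that keep a full experiment in CPU-minutes; the benchmark-scale
protocol values (64 filters / FC 1024 / FC 512, 28 epochs, batch 1000,
drops at 16 and 24, dropout 0.65) are all reachable through the same keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .synthetic import SyntheticSpec, generate, protocol_spec
from .train import TrainConfig, intrasubject_eval, losocv_eval
from .views import ViewConfig
from .features import WaveletConfig

__all__ = ["RunManifest", "load_config", "validate_config", "run_experiment",
           "DEFAULTS"]

DEFAULTS: dict = {
    "experiment": "intrasubject",
    "seed": 0,
    "outdir": None,
    "synthetic": {},
    "windows": {"window_ms": 200, "increment_ms": 100},
    "views": {"ids": [1, 2, 3],
              "wavelet": {"family": "db1", "levels": 3,
                          "extension_mode": "symmetric"},
              "minmax_scale": False},
    "model": {"variant": "hvpn", "conv_filters": 16, "fc_units": 128,
              "agg_units": 64, "dropout_rate": 0.1, "tap": "first",
              "flvp_bn_relu": True, "input_bn": True},
    "train": {"epochs": 10, "batch_size": 64, "lr_init": 0.1,
              "lr_drops": [6, 8], "momentum": 0.0, "weight_decay": 0.0,
              "loss_mode": "per_head_sum"},
    "pretrain": {"enabled": False, "epochs": 5, "dropout": 0.5},
    "adaptation": {"enabled": False},
}

_SYNTH_KEYS = {f.name for f in dataclasses.fields(SyntheticSpec)} - {"seed"}

#: Desk-scale within-subject study: the generator's default conditions
#: (4 subjects, 8 gestures, 6 trials per gesture, 10 electrodes at 100 Hz)
#: with a thin full-architecture model trained for 10 epochs at batch 64.
STUDY_INTRA: dict = {
    "experiment": "intrasubject",
    "synthetic": {},
    "windows": {"window_ms": 200, "increment_ms": 100},
    "model": {"conv_filters": 16, "fc_units": 128, "agg_units": 64,
              "dropout_rate": 0.1},
    "train": {"epochs": 10, "batch_size": 64, "lr_init": 0.1,
              "lr_drops": [6, 8]},
}

#: Desk-scale cross-subject study: a smaller gesture set with a large
#: per-subject electrode-gain spread, evaluated by LOSOCV with
#: BN-statistics adaptation (unadapted fold accuracies kept alongside).
STUDY_SHIFT: dict = {
    "experiment": "losocv",
    "synthetic": {"n_gestures": 6, "n_trials": 4, "trial_duration": 2.0,
                  "subject_shift_sd": 1.0},
    "windows": {"window_ms": 200, "increment_ms": 100},
    "model": {"conv_filters": 16, "fc_units": 128, "agg_units": 64,
              "dropout_rate": 0.1},
    "train": {"epochs": 10, "batch_size": 64, "lr_init": 0.1,
              "lr_drops": [6, 8]},
    "adaptation": {"enabled": True},
}


def _merge(base: dict, override: dict, path: str,
           errors: list[str]) -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key == "synthetic":
            bad = set(value) - _SYNTH_KEYS
            errors.extend(f"synthetic.{k}" for k in sorted(bad))
            out[key] = {k: v for k, v in value.items() if k in _SYNTH_KEYS}
        elif key not in base:
            errors.append(here)
        elif isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here, errors)
        else:
            out[key] = value
    return out


def validate_config(cfg: dict) -> dict:
    """Merge a partial config over the defaults; reject unknown keys."""
    errors: list[str] = []
    merged = _merge(DEFAULTS, cfg or {}, "", errors)
    if errors:
        raise ValueError("unknown config key(s): " + ", ".join(errors))
    if merged["experiment"] not in ("intrasubject", "losocv"):
        raise ValueError("experiment must be 'intrasubject' or 'losocv'")
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Everything needed to audit or repeat a run."""

    config: dict
    seed: int
    code_version: str
    dataset_fingerprint: str
    timings: dict[str, float] = field(default_factory=dict)
    metrics_path: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _n_heads(variant: str) -> int:
    pooled = ("hvpn", "hvpn-maxpool", "hvpn-avgpool")
    return 1 + (variant in pooled + ("vs-l1vp",)) \
        + (variant in pooled + ("vs-l2vp",))


def _fingerprint(recordings) -> str:
    h = hashlib.sha256()
    for rec in recordings:
        h.update(np.ascontiguousarray(rec.signal).tobytes())
        h.update(rec.gesture_label.tobytes())
    return h.hexdigest()[:16]


def _build_configs(cfg: dict):
    synth = SyntheticSpec(seed=cfg["seed"], **cfg["synthetic"])
    view_cfg = ViewConfig(
        wavelet=WaveletConfig(
            family=cfg["views"]["wavelet"]["family"],
            levels=cfg["views"]["wavelet"]["levels"],
            extension_mode=cfg["views"]["wavelet"]["extension_mode"]),
        minmax_scale=cfg["views"]["minmax_scale"])
    t = cfg["train"]
    train_cfg = TrainConfig(
        epochs=t["epochs"], batch_size=t["batch_size"],
        lr_init=t["lr_init"], lr_drops=tuple(t["lr_drops"]),
        momentum=t["momentum"], weight_decay=t["weight_decay"],
        loss_mode=t["loss_mode"], seed=cfg["seed"])
    return synth, view_cfg, train_cfg


def run_experiment(config: dict | str | Path,
                   outdir: str | Path | None = None):
    """Simulate, featurize, train and evaluate as configured.

    Returns ``(manifest, metrics)``; when an output directory is set the
    metrics and manifest are also written there as JSON.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    outdir = outdir or cfg["outdir"]

    synth, view_cfg, train_cfg = _build_configs(cfg)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    recordings = generate(synth)
    spec = protocol_spec(synth)
    timings["simulate_s"] = round(time.perf_counter() - t0, 3)

    common = dict(
        train_cfg=train_cfg, model_kwargs=cfg["model"],
        view_ids=tuple(cfg["views"]["ids"]), view_cfg=view_cfg,
        window_ms=cfg["windows"]["window_ms"],
        increment_ms=cfg["windows"]["increment_ms"])

    t0 = time.perf_counter()
    if cfg["experiment"] == "intrasubject":
        pre = None
        if cfg["pretrain"]["enabled"]:
            pre = dataclasses.replace(
                train_cfg, epochs=cfg["pretrain"]["epochs"],
                dropout=cfg["pretrain"]["dropout"])
        result = intrasubject_eval(recordings, spec, pretrain_cfg=pre,
                                   **common)
    else:
        result = losocv_eval(recordings, spec,
                             adaptation=cfg["adaptation"]["enabled"],
                             **common)
    timings["eval_s"] = round(time.perf_counter() - t0, 3)

    metrics = {
        "experiment": cfg["experiment"],
        "variant": cfg["model"]["variant"],
        "seed": cfg["seed"],
        "n_heads": _n_heads(cfg["model"]["variant"]),
        "per_unit_accuracy": {str(k): v
                              for k, v in result.per_unit_accuracy.items()},
        "mean_accuracy": result.mean_accuracy,
        "n_test_windows": result.extras.get("n_test_windows"),
    }
    if result.voting_mean is not None:
        metrics["voting_mean_accuracy"] = result.voting_mean
        metrics["voting_per_unit"] = {str(k): v
                                      for k, v in result.voting_per_unit.items()}
    if "unadapted_accuracy" in result.extras:
        metrics["unadapted_per_unit"] = {
            str(k): v for k, v in result.extras["unadapted_accuracy"].items()}
        metrics["unadapted_mean_accuracy"] = float(
            np.mean(list(result.extras["unadapted_accuracy"].values())))

    manifest = RunManifest(config=cfg, seed=cfg["seed"],
                           code_version=__version__,
                           dataset_fingerprint=_fingerprint(recordings),
                           timings=timings)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        manifest.metrics_path = str(metrics_path)
        (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest, metrics
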
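"""Experiment configuration, validation and the end-to-end runner.

A single YAML file describes one experiment: where the data comes from
(synthetic profile or CSV + schema), how to impute and split it, the
backbone, the training protocol and an optional ablation axis.  Unknown
keys are rejected; every stochastic stage consumes a seed derived from the
single root ``seed``.  ``run_experiment`` executes
impute -> split -> train -> evaluate (or the ablation grid) and writes an
:class:`ExperimentManifest` that fully determines a rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import BackboneConfig, build_backbone, save_checkpoint
from .data_model import (BOOLEAN, CONTINUOUS, ClinicalTable, FeatureSchema,
                         filter_rows_by_missingness, read_table)
from .imputation import BOOLEAN_STRATEGIES, ImputationPolicy
from .synthetic_data import (benchmark_spec, custom_spec, generate_clinical_dataset,
                             paper_profile)
from .training import (ABLATION_AXES, TrainConfig, TrialSummary, prepare_tables,
                       run_ablation, train)


class ConfigError(ValueError):
    """The configuration file violates the schema."""


_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "data": {"source": "synthetic", "profile": "benchmark", "path": None,
             "schema": None, "generator": None, "max_missing": 3},
    "imputation": {"strategy": "mode", "fill_value": 0.0,
                   "train_only_statistics": False},
    "split": {"train_fraction": 0.7},
    "model": {"kind": "mlp", "hidden_size": 256, "depth": 5,
              "embedding_size": 96, "dropout_rate": 0.3},
    "training": {"alpha": 2.0, "batch_size": 64, "epochs": 100,
                 "learning_rate": 1e-3, "optimizer": "adam", "n_trials": 5,
                 "negative_strategy": "max_minus", "negative_loss": "mse",
                 "include_negative": True},
    "ablation": {"axis": None, "values": None},
}
_TOP_DEFAULTS: Dict[str, Any] = {"seed": 0, "output_dir": "results"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated configuration plus the raw snapshot it came from."""

    data: Dict[str, Any]
    imputation: Dict[str, Any]
    split: Dict[str, Any]
    model: Dict[str, Any]
    training: Dict[str, Any]
    ablation: Dict[str, Any]
    seed: int
    output_dir: str
    snapshot: Dict[str, Any] = field(repr=False, default_factory=dict)


def _merge_section(name: str, given: Dict[str, Any]) -> Dict[str, Any]:
    defaults = dict(_DEFAULTS[name])
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    defaults.update(given)
    return defaults


def validate_config(raw: Optional[Dict[str, Any]]) -> ExperimentConfig:
    raw = dict(raw or {})
    sections = {}
    for name in _DEFAULTS:
        given = raw.pop(name, {}) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _merge_section(name, given)
    top = dict(_TOP_DEFAULTS)
    unknown = set(raw) - set(top)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    top.update(raw)

    cfg = ExperimentConfig(**sections, **top, snapshot={**{k: dict(v) for k, v in sections.items()}, **top})
    # cross-field validation delegated to the typed configs
    try:
        _train_config(cfg)
        _backbone_shape_free(cfg)
        _policy(cfg)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.data["source"] not in ("synthetic", "csv"):
        raise ConfigError("data.source must be 'synthetic' or 'csv'")
    if cfg.data["source"] == "csv" and not cfg.data["path"]:
        raise ConfigError("data.source=csv requires data.path")
    if cfg.data["source"] == "synthetic" and cfg.data["profile"] not in (
            "paper", "benchmark", "custom"):
        raise ConfigError("data.profile must be paper, benchmark or custom")
    if not 0.0 < cfg.split["train_fraction"] < 1.0:
        raise ConfigError("split.train_fraction must lie in (0, 1)")
    axis = cfg.ablation["axis"]
    if axis is not None and axis not in ABLATION_AXES:
        raise ConfigError(f"ablation.axis must be one of {ABLATION_AXES}")
    return cfg


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Load + validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return validate_config(raw)


def dump_config(cfg: ExperimentConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.snapshot, fh, sort_keys=True)


def _train_config(cfg: ExperimentConfig) -> TrainConfig:
    t = cfg.training
    return TrainConfig(alpha=float(t["alpha"]), batch_size=int(t["batch_size"]),
                       epochs=int(t["epochs"]), learning_rate=float(t["learning_rate"]),
                       optimizer_name=str(t["optimizer"]), n_trials=int(t["n_trials"]),
                       base_seed=int(cfg.seed),
                       negative_strategy=str(t["negative_strategy"]),
                       negative_loss=str(t["negative_loss"]),
                       include_negative=bool(t["include_negative"]))


def _backbone_shape_free(cfg: ExperimentConfig) -> None:
    m = cfg.model
    if m["kind"] not in ("mlp", "transformer_encoder"):
        raise ConfigError("model.kind must be mlp or transformer_encoder")
    if not 0.0 <= float(m["dropout_rate"]) < 1.0:
        raise ConfigError("model.dropout_rate must lie in [0, 1)")


def _backbone_config(cfg: ExperimentConfig, n_features: int,
                     n_classes: int) -> BackboneConfig:
    m = cfg.model
    return BackboneConfig(n_features=n_features, n_classes=n_classes,
                          kind=m["kind"], hidden_size=int(m["hidden_size"]),
                          depth=int(m["depth"]),
                          embedding_size=int(m["embedding_size"]),
                          dropout_rate=float(m["dropout_rate"]))


def _policy(cfg: ExperimentConfig) -> ImputationPolicy:
    i = cfg.imputation
    strategy = str(i["strategy"]).replace("-", "_")
    if strategy not in BOOLEAN_STRATEGIES:
        raise ConfigError(f"imputation.strategy must be one of {BOOLEAN_STRATEGIES}")
    seed = int(cfg.seed) + 101 if strategy in ("random", "bayesian") else None
    return ImputationPolicy(boolean_strategy=strategy,
                            fill_value=float(i["fill_value"]), seed=seed,
                            train_only_statistics=bool(i["train_only_statistics"]))


def schema_from_dict(d: Dict[str, Any]) -> FeatureSchema:
    """Build a :class:`FeatureSchema` from the YAML schema description."""
    try:
        features = d["features"]
        classes = d["classes"]
    except KeyError as exc:
        raise ConfigError(f"schema is missing key {exc}") from exc
    names, types, ranges = [], [], {}
    for f in features:
        names.append(str(f["name"]))
        ftype = str(f["type"])
        if ftype not in (BOOLEAN, CONTINUOUS):
            raise ConfigError(f"feature {f['name']!r}: type must be boolean/continuous")
        types.append(ftype)
        if ftype == CONTINUOUS and "range" in f:
            lo, hi = f["range"]
            ranges[str(f["name"])] = (float(lo), float(hi))
    return FeatureSchema(feature_names=tuple(names), feature_types=tuple(types),
                         class_labels=tuple(str(c) for c in classes),
                         continuous_ranges=ranges,
                         label_column=str(d.get("label_column", "label")))


def load_schema(path: Union[str, Path]) -> FeatureSchema:
    with open(path) as fh:
        return schema_from_dict(yaml.safe_load(fh))


def load_dataset(cfg: ExperimentConfig) -> Tuple[ClinicalTable, str]:
    """Materialize the configured dataset; returns (table, content hash)."""
    d = cfg.data
    if d["source"] == "csv":
        schema = load_schema(d["schema"]) if isinstance(d["schema"], str) \
            else schema_from_dict(d["schema"] or {})
        table = read_table(d["path"], schema)
        digest = hashlib.sha256(Path(d["path"]).read_bytes()).hexdigest()[:16]
    else:
        gen_seed = int(cfg.seed) + 100
        if d["profile"] == "paper":
            spec = paper_profile(seed=gen_seed)
        elif d["profile"] == "benchmark":
            spec = benchmark_spec(seed=gen_seed)
        else:
            g = d["generator"] or {}
            spec = custom_spec(seed=gen_seed, **g)
        table = generate_clinical_dataset(spec)
        digest = hashlib.sha256(repr(dataclasses.asdict(spec)).encode()).hexdigest()[:16]
    return filter_rows_by_missingness(table, int(d["max_missing"])), digest


@dataclass(frozen=True)
class ExperimentManifest:
    """Everything needed to reproduce one experiment bit-for-bit."""

    config: Dict[str, Any]
    seeds: Dict[str, Any]
    version: str
    input_hash: str
    metrics: Dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_experiment(cfg: ExperimentConfig) -> ExperimentManifest:
    """Execute the configured pipeline and write all artifacts.

    Writes ``manifest.json``, ``metrics.json`` and either ``history.csv``
    plus a ``model.npz`` checkpoint (plain run) or ``ablation.csv``
    (ablation run) under ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, digest = load_dataset(cfg)
    train_cfg = _train_config(cfg)
    backbone_cfg = _backbone_config(cfg, dataset.schema.n_features,
                                    dataset.schema.n_classes)
    policy = _policy(cfg)
    fraction = float(cfg.split["train_fraction"])
    seeds = {"root": cfg.seed, "generator": cfg.seed + 100,
             "imputation": policy.seed,
             "trials": [cfg.seed + t for t in range(train_cfg.n_trials)]}

    axis = cfg.ablation["axis"]
    if axis is not None:
        table = run_ablation(axis, train_cfg, backbone_cfg, dataset, policy,
                             train_fraction=fraction,
                             values=cfg.ablation["values"])
        table.to_csv(out / "ablation.csv", index=False)
        metrics = {"ablation": table.to_dict(orient="records")}
    else:
        accs, f1s = [], []
        first_history = None
        model = None
        for t, seed in enumerate(seeds["trials"]):
            train_t, test_t = prepare_tables(dataset, policy, fraction, seed)
            model = build_backbone(backbone_cfg, seed=seed)
            history = train(model, train_t, test_t,
                            dataclasses.replace(train_cfg, base_seed=seed))
            if t == 0:
                first_history = history
            if history.epoch_accuracy:
                accs.append(history.epoch_accuracy[-1])
                f1s.append(history.epoch_f1[-1])
        if first_history is not None and first_history.steps:
            first_history.step_frame().to_csv(out / "history.csv", index=False)
            first_history.epoch_frame().to_csv(out / "epochs.csv", index=False)
        if model is not None:
            save_checkpoint(model, out / "model.npz")
        summary = TrialSummary(float(np.mean(accs)) if accs else float("nan"),
                               float(np.std(accs)) if accs else 0.0,
                               float(np.mean(f1s)) if f1s else float("nan"),
                               float(np.std(f1s)) if f1s else 0.0,
                               tuple(accs), tuple(f1s))
        metrics = {"accuracy_mean": summary.accuracy_mean,
                   "accuracy_std": summary.accuracy_std,
                   "f1_mean": summary.f1_mean, "f1_std": summary.f1_std,
                   "per_trial_accuracy": list(summary.accuracies),
                   "per_trial_f1": list(summary.f1_scores)}

    manifest = ExperimentManifest(config=cfg.snapshot, seeds=seeds,
                                  version=__version__, input_hash=digest,
                                  metrics=metrics)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
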
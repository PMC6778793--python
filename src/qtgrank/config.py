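"""Run configuration: species profiles, YAML loading, report writing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, fields

import yaml

__all__ = ["SpeciesProfile", "PROFILES", "RunConfig", "load_config", "run_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesProfile:
    """Species-specific training defaults (positives:negatives ratio)."""

    name: str
    train_neg_ratio: int

    def __post_init__(self) -> None:
        if self.train_neg_ratio < 1:
            raise ValueError("train_neg_ratio must be >= 1")


PROFILES: dict[str, SpeciesProfile] = {
    "arabidopsis": SpeciesProfile("arabidopsis", train_neg_ratio=20),
    "rice": SpeciesProfile("rice", train_neg_ratio=5),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration shared by the CLI subcommands."""

    species_profile: str = "arabidopsis"
    folds: int = 5
    positive_resplits: int = 50
    negative_resamples: int = 50
    train_neg_ratio: int = 20
    test_neg_ratio: int = 200
    n_trees: int = 100
    max_features_per_tree: int = 9
    decision_threshold: float = 0.5
    n_models: int = 5000
    flank: int = 200
    seed: int = 0


def load_config(path=None, **overrides) -> RunConfig:
    """Resolve a run configuration from an optional YAML file plus flags.

    Flag overrides win over file values (a note is logged when they
    conflict).  The species profile sets ``train_neg_ratio`` unless either
    source pins it explicitly.  Unknown keys are a hard error listing the
    valid ones.
    """
    valid = {f.name for f in fields(RunConfig)}
    file_values: dict = {}
    if path is not None:
        with open(path) as fh:
            try:
                loaded = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"{path}: cannot parse config: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - valid
        if unknown:
            raise ValueError(
                f"{path}: unknown config key(s) {sorted(unknown)}; "
                f"valid keys: {sorted(valid)}"
            )
        file_values = loaded
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in set(file_values) & set(overrides):
        if file_values[key] != overrides[key]:
            logger.info(
                "config key %r: flag value %r overrides file value %r",
                key, overrides[key], file_values[key],
            )
    values = {**file_values, **overrides}
    profile_name = values.get("species_profile", RunConfig.species_profile)
    if profile_name not in PROFILES:
        raise ValueError(
            f"unknown species profile {profile_name!r}; valid: {sorted(PROFILES)}"
        )
    if "train_neg_ratio" not in values:
        values["train_neg_ratio"] = PROFILES[profile_name].train_neg_ratio
    config = RunConfig(**values)
    logger.info("resolved configuration: %s", dataclasses.asdict(config))
    return config


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_report(results: dict, out_path, config: RunConfig | None = None) -> None:
    """Write a JSON machine report with provenance (version, seed, config)."""
    from . import __version__

    report = {
        "qtgrank_version": __version__,
        "results": results,
    }
    if config is not None:
        report["seed"] = config.seed
        report["config"] = dataclasses.asdict(config)
        report["config_hash"] = _config_hash(config)
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
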
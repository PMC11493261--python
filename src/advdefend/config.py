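"""Experiment configuration: schema, defaults, parsing, seed fan-out.

An empty config file yields the full defaults: the synthetic benchmark
dataset, the tinycnn classifier, both attack families over the canonical
epsilon grid (0.001, 0.006, 0.05, 0.1, 0.4), and the autoencoder defense
with its published training recipe.  Unknown keys are rejected with the
offending field path.

One global seed fans out deterministically to per-stage seeds via
``numpy.random.SeedSequence([global_seed, crc32(stage_name)])`` (truncated
below 2**31), so every stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .attacks import DEFAULT_EPSILONS
from .errors import ConfigError


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DatasetBlock(_Block):
    source: str = "synthetic"          # 'synthetic' | 'folder'
    root: str | None = None            # folder source only
    image_size: int = 64
    n_per_class_per_split: dict[str, int] = {
        "train": 100, "test": 100, "validation": 100}
    noise_sd: float = 0.03

    @field_validator("source")
    @classmethod
    def _source(cls, v):
        if v not in ("synthetic", "folder"):
            raise ValueError("source must be 'synthetic' or 'folder'")
        return v


class ClassifierBlock(_Block):
    backbone: str = "tinycnn"
    width: int = 32
    stacked: bool = False              # fuse two backbones
    second_backbone: str = "tinycnn"
    learning_rate: float = 2e-3        # tinycnn desk-scale default
    epochs: int = 20
    batch_size: int = 21


class AttackBlock(_Block):
    families: list[str] = ["fgsm", "pgd"]
    epsilons: list[float] = list(DEFAULT_EPSILONS)
    n_iter: int = 10
    step_size: float | None = None     # None -> eps/4
    random_start: bool = False

    @field_validator("families")
    @classmethod
    def _fams(cls, v):
        for f in v:
            if f not in ("fgsm", "pgd"):
                raise ValueError(f"unknown attack family '{f}'")
        return v


class DenoiserBlock(_Block):
    enabled: bool = True
    learning_rate: float = 1e-3
    epochs: int = 20                   # desk-scale; published recipe uses 30
    batch_size: int = 32
    noisy_input: bool = False
    val_fraction: float = 0.1


class EvaluationBlock(_Block):
    split: str = "test"
    apply_denoiser_to_clean: bool = False

    @field_validator("split")
    @classmethod
    def _split(cls, v):
        if v not in ("train", "test", "validation"):
            raise ValueError(f"unknown split '{v}'")
        return v


class ExperimentConfig(_Block):
    dataset: DatasetBlock = DatasetBlock()
    classifier: ClassifierBlock = ClassifierBlock()
    attack: AttackBlock = AttackBlock()
    denoiser: DenoiserBlock = DenoiserBlock()
    evaluation: EvaluationBlock = EvaluationBlock()
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def parse_config(path: str | Path | None = None,
                 overrides: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML/JSON config file; fill all defaults.

    ``path=None`` or an empty file yields the defaults.  Schema violations
    raise :class:`ConfigError` naming the offending field.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            raw = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {p}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    if overrides:
        raw = {**raw, **overrides}
    try:
        return ExperimentConfig(**raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"]
            for e in exc.errors())
        raise ConfigError(f"invalid config: {locs}") from exc
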
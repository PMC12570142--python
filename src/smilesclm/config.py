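"""YAML run configuration for end-to-end pipeline runs.

A run config gathers the per-stage parameter blocks (corpus, curation,
model, training, generation, split, evaluation) plus the single global seed
and the output directory.  Unknown keys — at the top level or inside any
block — are rejected with a message naming them, so a typo never silently
falls back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path

import yaml

from .fixtures import FixtureSpec
from .generation import GenerationConfig
from .model import ClmConfig
from .training import TrainingConfig


class RunConfigError(ValueError):
    pass


#: per-block allowed keys.  Model/training/generation blocks mirror their
#: dataclasses minus the fields the pipeline derives itself (vocabulary size,
#: context length, per-stage seeds — all derived from the corpus and the
#: global seed).
_DERIVED = {"seed", "vocab_size", "max_len", "n_samples"}
_BLOCK_KEYS = {
    "fixture": {f.name for f in dataclass_fields(FixtureSpec)} - _DERIVED,
    "curation": {"length_trim"},
    "model": {f.name for f in dataclass_fields(ClmConfig)} - _DERIVED,
    "training": {f.name for f in dataclass_fields(TrainingConfig)} - _DERIVED,
    "generation": ({f.name for f in dataclass_fields(GenerationConfig)}
                   - {"seed"}),
    "split": {"holdout_fraction", "threshold"},
    "evaluation": {"fcd_subset"},
}
_TOP_KEYS = {"seed", "workdir", "input", *_BLOCK_KEYS}


@dataclass
class RunConfig:
    """Validated parameter blocks for one pipeline run.

    ``input`` points at an existing SMILES file; when absent, the corpus is
    synthesized from the ``fixture`` block.
    """

    seed: int = 0
    workdir: Path = Path("run")
    input: Path | None = None
    fixture: dict = field(default_factory=dict)
    curation: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    generation: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)


def _check_keys(name: str, block: dict, allowed: set[str]) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise RunConfigError(
            f"unknown keys in {name!r} block: {unknown}; allowed: {sorted(allowed)}")


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys raise
    :class:`RunConfigError` naming the offending keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise RunConfigError(f"{path}: top level must be a mapping")
    _check_keys("top-level", data, _TOP_KEYS)
    for block_name, allowed in _BLOCK_KEYS.items():
        block = data.get(block_name, {})
        if block is None:
            block = {}
        if not isinstance(block, dict):
            raise RunConfigError(f"{block_name!r} block must be a mapping")
        _check_keys(block_name, block, allowed)
        data[block_name] = block
    cfg = RunConfig(**{k: v for k, v in data.items()})
    cfg.workdir = Path(cfg.workdir)
    if cfg.input is not None:
        cfg.input = Path(cfg.input)
    return cfg
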
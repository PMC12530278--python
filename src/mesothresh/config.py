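"""Run configuration: analysis-wide knobs loaded from YAML/JSON with strict key checking.

Every field has a default matching the study design this package emulates
(999 permutations, rarefaction to 5258 reads, p < 0.01 model selection,
three-clause pathway filter). Unknown keys in a config file are an error so
that typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates an invariant."""


@dataclass
class RunConfig:
    """Analysis-stage configuration shared by the CLI subcommands."""

    n_permutations: int = 999
    rng_seed: int = 0
    rarefaction_depth: int = 5258
    alpha_model_selection: float = 0.01
    pathway_p_threshold: float = 0.01
    pathway_min_abs_log2fc: float = 2.0
    pathway_min_taxa: int = 5
    ordination_dimensions: int = 2
    impute: str | None = None  # None = missing env values are an error; "mean" imputes

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.rarefaction_depth < 1:
            raise ConfigError("rarefaction_depth must be >= 1")
        for key in ("alpha_model_selection", "pathway_p_threshold",
                    "pathway_min_abs_log2fc"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0")
        if self.pathway_min_taxa < 1:
            raise ConfigError("pathway_min_taxa must be >= 1")
        if self.ordination_dimensions < 1:
            raise ConfigError("ordination_dimensions must be >= 1")
        if self.impute not in (None, "mean"):
            raise ConfigError("impute must be null or 'mean'")


def _from_mapping(cls: type, data: dict[str, Any], source: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown} in {source}; "
            f"known keys: {sorted(known)}"
        )
    try:
        return cls(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"bad config in {source}: {exc}") from exc


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML (or JSON) file, strictly."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return _from_mapping(RunConfig, data, str(path))


def dump_config(cfg: Any, path: str | Path) -> None:
    """Write any config dataclass as JSON (for provenance logging)."""
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2, default=str))
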
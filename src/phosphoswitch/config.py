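"""Run-configuration loading and validation (YAML/JSON).

A config file carries model parameters, a variant flag, optional
protocol/grid/scenario settings, a seed and an output directory.
Unknown keys are rejected by name so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .params import RATE_NAMES, TOTAL_NAMES, ModelParameters
from .species import ConfigurationError, VARIANTS

_PARAM_FIELDS = set(RATE_NAMES + TOTAL_NAMES)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration_s: float = 2400.0
    sampling_times_s: list[float] = Field(
        default_factory=lambda: [0.0, 300.0, 600.0, 1200.0, 2400.0]
    )


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 25
    lo: float = 1e-6
    hi: float = 1e-2


class RunConfig(BaseModel):
    """Validated run configuration with defaults documented per field."""

    model_config = ConfigDict(extra="forbid")

    parameters: dict[str, float] = Field(default_factory=dict)
    variant: str = "WT"
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    scenario: str | None = None
    seed: int = 0
    output_dir: str = "."

    def model_post_init(self, __context) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        unknown = set(self.parameters) - _PARAM_FIELDS
        if unknown:
            raise ValueError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )

    def model_parameters(self) -> ModelParameters:
        """Effective parameters with the variant override applied once."""
        return ModelParameters(**self.parameters).with_variant(self.variant)

    def content_hash(self) -> str:
        """Stable hash of the effective configuration, for output audits."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data)}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective config back out (the lossless metadata echo)."""
    path = Path(path)
    payload = config.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, default=float))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
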
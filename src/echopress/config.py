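"""Pipeline configuration: schema, validation, YAML/JSON round-trip.

A single config file drives every stage.  All physical constants are
explicit; layer constants left null are derived at run time by the
endpoint calibration (Z0, A0, posterior gain) or default to Z0 (Z3).
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TransducerConfig(_Section):
    center_frequency: float = Field(4.7e7, gt=0)
    fractional_bandwidth: float = Field(0.62, gt=0, lt=2)


class AcquisitionConfig(_Section):
    sampling_rate: float = Field(1e9, gt=0)
    n_alines: int = Field(10, ge=1)
    n_repeats: int = Field(3, ge=1)
    noise_sd: float | None = Field(None, ge=0)
    record_length: int = Field(4096, ge=16)


class LayersConfig(_Section):
    # Null impedance/amplitude constants are filled by the endpoint calibration.
    Z0: float | None = Field(None, gt=0)
    Z3: float | None = Field(None, gt=0)
    A0: float | None = Field(None, gt=0)
    posterior_gain: float | None = Field(None, gt=0)
    cornea_thickness: float = Field(0.8e-3, gt=0)
    cornea_speed: float = Field(1580.0, gt=0)


class CalibrationConfig(_Section):
    iop_low: float = 10.0
    iop_high: float = 50.0
    Z1_low: float = Field(1.5399, gt=0)
    Z1_high: float = Field(1.5519, gt=0)
    Z2_low: float = Field(1.5393, gt=0)
    Z2_high: float = Field(1.5698, gt=0)
    ant_amp_low: float = Field(1.6347, gt=0)
    ant_amp_high: float = Field(2.1454, gt=0)
    post_amp_low: float = Field(0.5778, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "CalibrationConfig":
        if not self.iop_low < self.iop_high:
            raise ValueError("iop_low must be < iop_high")
        return self


class AnalysisConfig(_Section):
    iops: list[float] = Field(default_factory=lambda: [10.0, 20.0, 30.0, 40.0, 50.0])
    min_separation: float = Field(0.2e-6, gt=0)
    window_frac: float = Field(0.7, gt=0, lt=1)
    per_level: bool = True  # correlate per-IOP means (False: unaggregated rows)

    @model_validator(mode="after")
    def _iops_ok(self) -> "AnalysisConfig":
        if not self.iops:
            raise ValueError("iops must be nonempty")
        if any(b <= a for a, b in zip(self.iops, self.iops[1:])):
            raise ValueError("iops must be strictly increasing")
        return self


class PipelineConfig(_Section):
    seed: int
    output_dir: str | None = None
    transducer: TransducerConfig = Field(default_factory=TransducerConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    layers: LayersConfig = Field(default_factory=LayersConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        offending = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config ({path}): offending keys: {offending}") from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config as YAML (JSON-compatible values only)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for provenance logging."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
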
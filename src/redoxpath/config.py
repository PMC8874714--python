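"""Layered, validated run configuration.

Values resolve as defaults < config file < explicit overrides.  Unknown keys
are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .et_model import CalibrationPoint

__all__ = ["RunConfig", "load_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PointCfg(_Strict):
    distance: float = Field(gt=0)
    rate: float = Field(gt=0)

    def as_point(self) -> CalibrationPoint:
        return CalibrationPoint(distance=self.distance, rate=self.rate)


class CalibrationCfg(_Strict):
    points: list[PointCfg]
    anchor: PointCfg
    anchor_tolerance_factor: float = Field(default=1.2, ge=1.0)

    @field_validator("points")
    @classmethod
    def _two_points(cls, v: list[PointCfg]) -> list[PointCfg]:
        if len(v) != 2:
            raise ValueError(f"calibration.points needs exactly 2 entries, got {len(v)}")
        return v


class DomainsCfg(_Strict):
    ranges: dict[str, tuple[int, int]]
    residue_codes: dict[str, str] = {"HEM": "HEM", "FMN": "FMN", "FAD": "FAD"}


class EquilibriumCfg(_Strict):
    kd: float = Field(gt=0)
    concentrations: list[float]

    @field_validator("concentrations")
    @classmethod
    def _positive(cls, v: list[float]) -> list[float]:
        if any(c <= 0 for c in v):
            raise ValueError("equilibrium.concentrations must be positive")
        return v


class PathwayCfg(_Strict):
    kcat: dict[str, float]
    consistency_bounds: tuple[float, float] = (1.0 / 3.0, 3.0)
    aromatic_contact_threshold: float = Field(default=4.0, gt=0)
    cross_rejection_rate: float = Field(default=1e-7, gt=0)
    aromatic_residues: list[int] = [262]


class RunConfig(_Strict):
    calibration: CalibrationCfg
    domains: DomainsCfg
    equilibrium: EquilibriumCfg
    pathway: PathwayCfg
    seed: int = 0


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _default_dict() -> dict[str, Any]:
    text = resources.files("redoxpath").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def default_config() -> RunConfig:
    """The shipped CYP102A1 profile."""
    return RunConfig.model_validate(_default_dict())


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Defaults, optionally layered with a YAML file and explicit overrides."""
    data = _default_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = _deep_merge(data, user)
    if overrides:
        data = _deep_merge(data, overrides)
    return RunConfig.model_validate(data)
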
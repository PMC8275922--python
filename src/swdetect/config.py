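"""YAML configuration for the detector, filters, synthesis and grids.

One file with optional ``detector``, ``filter``, ``synth`` and ``grid``
sections; every field defaults to the package's clinical operating point.
Unknown sections or keys are rejected before any computation runs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .detector import DetectorParams
from .preprocess import FilterSpec
from .synth import ArtifactSpec, SynthConfig
from .trainer import GridSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "save_params"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclasses.dataclass
class RunConfig:
    detector: DetectorParams
    filter: FilterSpec
    synth: SynthConfig
    grid: GridSpec


def _build(cls, section: Mapping[str, Any], name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in [{name}]: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    coerced = dict(section)
    if cls is SynthConfig and "artifact_spec" in coerced:
        coerced["artifact_spec"] = tuple(
            ArtifactSpec(**a) if isinstance(a, dict) else ArtifactSpec(*a)
            for a in coerced["artifact_spec"]
        )
    if cls is SynthConfig and "channel_labels" in coerced:
        coerced["channel_labels"] = tuple(coerced["channel_labels"])
    if cls is GridSpec:
        coerced = {k: tuple(v) for k, v in coerced.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; a missing path yields all defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded
    known = {"detector", "filter", "synth", "grid"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}; allowed: {sorted(known)}")
    return RunConfig(
        detector=_build(DetectorParams, raw.get("detector", {}), "detector"),
        filter=_build(FilterSpec, raw.get("filter", {}), "filter"),
        synth=_build(SynthConfig, raw.get("synth", {}), "synth"),
        grid=_build(GridSpec, raw.get("grid", {}), "grid"),
    )


def save_params(params: DetectorParams, path: str | Path) -> None:
    """Write fitted detector parameters as a config file (detector section)."""
    payload = {"detector": dataclasses.asdict(params)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
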
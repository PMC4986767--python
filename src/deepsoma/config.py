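"""YAML (de)serialisation of the pipeline's parameter dataclasses.

One document with optional ``caller``, ``filters``, ``sim`` and ``run``
sections; unknown keys are rejected so typos in threshold names fail loudly.
"""

from __future__ import annotations

import dataclasses
from typing import Any, TypeVar

import yaml

from .calling import CallerParams
from .filters import FilterConfig
from .simulate import ArtifactSite, PlantedVariant, SimConfig

T = TypeVar("T")


def _from_mapping(cls: type[T], data: dict[str, Any]) -> T:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def sim_config_from_dict(data: dict[str, Any]) -> SimConfig:
    data = dict(data)
    plants = [_from_mapping(PlantedVariant,
                            {**d, "samples": tuple(d.get("samples", ()))})
              for d in data.pop("somatic_plants", [])]
    arts = [_from_mapping(ArtifactSite, d)
            for d in data.pop("artifact_sites", [])]
    if "samples" in data:
        data["samples"] = tuple(data["samples"])
    cfg = _from_mapping(SimConfig, data)
    cfg.somatic_plants = plants
    cfg.artifact_sites = arts
    return cfg


def load_config(path) -> dict[str, Any]:
    """Load a YAML config file; returns a dict with any of the typed
    sections ('caller', 'filters', 'sim') instantiated."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = dict(raw)
    if "caller" in raw:
        out["caller"] = _from_mapping(CallerParams, raw["caller"] or {})
    if "filters" in raw:
        out["filters"] = _from_mapping(FilterConfig, raw["filters"] or {})
    if "sim" in raw:
        out["sim"] = sim_config_from_dict(raw["sim"] or {})
    return out


def dump_config(sections: dict[str, Any], path) -> None:
    enc = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
           for k, v in sections.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(enc, fh, sort_keys=True)
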
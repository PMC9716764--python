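"""Configuration handling: defaults, YAML loading, dataclass assembly."""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import yaml

from .compensation import ThresholdSpec
from .errors import ConfigError
from .exposure import CutPointSpec
from .preprocessing import NonwearParams, ValidityParams
from .synthetic_data import CohortConfig, PhenotypeMix

ANALYSIS_DEFAULTS: dict = {
    "nonwear": {"window_min": 90, "tolerance_min": 2, "flank_min": 30},
    "validity": {"min_wear_min": 480, "min_weekdays": 3, "min_weekend_days": 1},
    "cuts": {"sedentary_max": 180, "light_min": 181, "light_max": 3360, "mvpa_min": 3361},
    "exposure": {"min_segment_wear_min": 60},
    "threshold": {"z": 1.645, "variant": "paper_literal"},
}


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of all processing/classification parameters."""

    nonwear: NonwearParams = NonwearParams()
    validity: ValidityParams = ValidityParams()
    cuts: CutPointSpec = CutPointSpec()
    min_segment_wear_min: int = 60
    threshold: ThresholdSpec = ThresholdSpec()


def load_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def _merged(section: str, overrides: dict) -> dict:
    base = dict(ANALYSIS_DEFAULTS[section])
    for key, value in overrides.items():
        if key not in base:
            raise ConfigError(f"unknown config key {section}.{key}")
        base[key] = value
    return base


def analysis_config_from_dict(raw: dict | None) -> AnalysisConfig:
    """Build an AnalysisConfig from a (possibly partial) nested mapping."""
    raw = raw or {}
    unknown = set(raw) - set(ANALYSIS_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    nonwear = _merged("nonwear", raw.get("nonwear", {}))
    validity = _merged("validity", raw.get("validity", {}))
    cuts = _merged("cuts", raw.get("cuts", {}))
    exposure = _merged("exposure", raw.get("exposure", {}))
    threshold = _merged("threshold", raw.get("threshold", {}))
    return AnalysisConfig(
        nonwear=NonwearParams(**nonwear),
        validity=ValidityParams(**validity),
        cuts=CutPointSpec(**cuts),
        min_segment_wear_min=int(exposure["min_segment_wear_min"]),
        threshold=ThresholdSpec(**threshold),
    )


_COHORT_REQUIRED = ("n_girls", "seed")


def cohort_config_from_dict(raw: dict) -> CohortConfig:
    """Build a CohortConfig from a mapping; missing required keys are named."""
    for key in _COHORT_REQUIRED:
        if key not in raw:
            raise ConfigError(f"missing required config key 'cohort.{key}'")
    kwargs: dict = {}
    field_names = {f.name for f in dataclasses.fields(CohortConfig)}
    for key, value in raw.items():
        if key not in field_names:
            raise ConfigError(f"unknown config key 'cohort.{key}'")
        kwargs[key] = value
    if "start_date" in kwargs and isinstance(kwargs["start_date"], str):
        kwargs["start_date"] = dt.date.fromisoformat(kwargs["start_date"])
    for mix_key in ("weekday_mix", "weekend_mix"):
        if mix_key in kwargs and isinstance(kwargs[mix_key], dict):
            kwargs[mix_key] = PhenotypeMix(**kwargs[mix_key])
    if "profiles" in kwargs:
        kwargs["profiles"] = {k: tuple(v) for k, v in kwargs["profiles"].items()}
    return CohortConfig(**kwargs)


def resolved_analysis_dict(cfg: AnalysisConfig) -> dict:
    """Serialisable view of a resolved analysis config (for provenance)."""
    return {
        "nonwear": dataclasses.asdict(cfg.nonwear),
        "validity": dataclasses.asdict(cfg.validity),
        "cuts": dataclasses.asdict(cfg.cuts),
        "exposure": {"min_segment_wear_min": cfg.min_segment_wear_min},
        "threshold": dataclasses.asdict(cfg.threshold),
    }
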
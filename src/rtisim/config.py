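"""Run configuration: structured defaults, strict YAML loading, hashing.

Every published parameter lives in the dataclass defaults of the modules
it belongs to; this module assembles them into a single ``RunConfig`` and
reads overrides from a YAML (or JSON) file.  Unknown keys and out-of-range
values are rejected with an error naming the offending field.  An empty
file yields the full base case.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .economics import CostParams
from .epidemiology import RiskEffects
from .errors import ConfigurationError
from .parameters import AbsenteeismParams
from .scenarios import CURRENT_INTAKE_FRACTION, ScenarioSpec, default_scenarios
from .synthpop import PopulationConfig

UPTAKE_PRESETS = {"generalized": 1.0, "current": CURRENT_INTAKE_FRACTION, "none": 0.0}


@dataclass(frozen=True)
class ProfileConfig:
    """Seasonal onset profile: 'flat' or 'winter_peak'."""

    preset: str = "winter_peak"
    peak_day: int = 35
    concentration: float = 2.0


@dataclass(frozen=True)
class IncidenceConfig:
    """Calibration anchors and the age-based incidence contrast."""

    child_adult_incidence_ratio: float = 2.85
    calibration_target_episodes: float = 24_671.0
    calibration_reference_cohort: int = 329_256
    target_unvaccinated_episode_share: float = 0.554


@dataclass(frozen=True)
class DurationConfig:
    """Episode-duration dispersion (CV) and floor; the mean comes from the
    scenario."""

    dispersion: float = 0.5
    minimum_days: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    incidence: IncidenceConfig = field(default_factory=IncidenceConfig)
    risk: RiskEffects = field(default_factory=RiskEffects)
    duration: DurationConfig = field(default_factory=DurationConfig)
    scenario: ScenarioSpec = field(
        default_factory=lambda: default_scenarios()["yhec"])
    absenteeism: AbsenteeismParams = field(default_factory=AbsenteeismParams)
    costs: CostParams = field(default_factory=CostParams)
    seed: int = 1


def default_config(scenario: str = "yhec") -> RunConfig:
    specs = default_scenarios()
    if scenario not in specs:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {sorted(specs)}")
    return RunConfig(scenario=specs[scenario])


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"config section {path!r} must be a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown config key {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for key, value in data.items():
        if key == "age_distribution":
            value = tuple(tuple(band) for band in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid value in section {path!r}: {exc}") from exc


def _build_scenario(data: dict) -> ScenarioSpec:
    if not isinstance(data, dict):
        raise ConfigurationError("config section 'scenario' must be a mapping")
    name = data.get("name", "yhec")
    specs = default_scenarios()
    if name not in specs:
        raise ConfigurationError(
            f"unknown scenario.name {name!r}; expected one of {sorted(specs)}")
    base = specs[name]
    overrides = {k: v for k, v in data.items() if k != "name"}
    names = {f.name for f in fields(ScenarioSpec)}
    unknown = set(overrides) - names
    if unknown:
        raise ConfigurationError(f"unknown config key scenario.{sorted(unknown)[0]}")
    try:
        return dataclasses.replace(base, **overrides)
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid value in section 'scenario': {exc}") from exc


_SECTIONS = {
    "population": PopulationConfig,
    "profile": ProfileConfig,
    "incidence": IncidenceConfig,
    "risk": RiskEffects,
    "duration": DurationConfig,
    "absenteeism": AbsenteeismParams,
    "costs": CostParams,
}


def config_from_mapping(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigurationError("top-level config must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"scenario", "seed"}
    if unknown:
        raise ConfigurationError(f"unknown config key {sorted(unknown)[0]}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_dataclass(cls, data[section], section)
    if "scenario" in data:
        kwargs["scenario"] = _build_scenario(data["scenario"])
    if "seed" in data:
        seed = data["seed"]
        if not isinstance(seed, int) or seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        kwargs["seed"] = seed
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file; an empty file gives the full base case."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    return config_from_mapping(data)


def _as_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def dump_config(config: RunConfig) -> dict:
    """Plain-dict form of a config; round-trips through config_from_mapping."""
    return _as_plain(config)


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration for provenance."""
    payload = json.dumps(dump_config(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def replace_in_config(config: RunConfig, path: str, value) -> RunConfig:
    """Return a config with the dotted ``path`` (e.g.
    ``scenario.antibiotic_rr``) replaced by ``value``."""
    parts = path.split(".")

    def _replace(obj, parts):
        name = parts[0]
        if not is_dataclass(obj) or name not in {f.name for f in fields(obj)}:
            raise ConfigurationError(f"unknown config path {path!r}")
        if len(parts) == 1:
            return dataclasses.replace(obj, **{name: value})
        return dataclasses.replace(obj, **{name: _replace(getattr(obj, name), parts[1:])})

    return _replace(config, parts)
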
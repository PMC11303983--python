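"""Run configuration: nested blocks, YAML round-trip, dotted-key overrides.

A :class:`RunConfig` gathers everything a reproducible run needs: the model
parameters, the gradient settings, the integration protocol, the analysis
conventions and the temporal-mode schedule.  Defaults reproduce the symmetric
reference configuration end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import Any, Mapping

import yaml

from .model import ModelParameters, SystemState
from .simulate import SimulationSettings

__all__ = [
    "EnvironmentConfig",
    "AnalysisConfig",
    "TemporalConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "apply_overrides",
]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


@dataclass(frozen=True)
class EnvironmentConfig:
    n_steps: int = 101
    factor: float = 1.0


@dataclass(frozen=True)
class AnalysisConfig:
    metric: str = "log10"
    no_tipping_floor: float = 0.5


@dataclass(frozen=True)
class TemporalConfig:
    phase_durations: tuple[float, float, float] = (5.0e5, 5.0e5, 5.0e5)
    n_steps_per_ramp: int = 50
    record_every: float = 200.0


@dataclass(frozen=True)
class RunConfig:
    parameters: ModelParameters = field(default_factory=ModelParameters)
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "parameters": self.parameters.to_dict(),
            "environment": asdict(self.environment),
            "simulation": asdict(self.simulation),
            "analysis": asdict(self.analysis),
            "temporal": asdict(self.temporal),
        }
        d["simulation"]["initial_state"] = {
            k: getattr(self.simulation.initial_state, k)
            for k in ("N_CB", "N_SB", "O", "S", "P")
        }
        d["temporal"]["phase_durations"] = list(self.temporal.phase_durations)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known_blocks = {"parameters", "environment", "simulation", "analysis", "temporal"}
        unknown = set(d) - known_blocks
        if unknown:
            raise ConfigError(f"unknown configuration block(s): {sorted(unknown)}")

        def build(block: str, factory, mapping: Mapping[str, Any]):
            names = {f.name for f in fields(factory)}
            bad = set(mapping) - names
            if bad:
                raise ConfigError(f"unknown key(s) in '{block}': {sorted(bad)}")
            try:
                return factory(**mapping)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"invalid value in '{block}': {err}") from err

        params = build("parameters", ModelParameters, d.get("parameters", {}))
        env = build("environment", EnvironmentConfig, d.get("environment", {}))
        sim_d = dict(d.get("simulation", {}))
        if "initial_state" in sim_d:
            st = sim_d["initial_state"]
            if not isinstance(st, Mapping):
                raise ConfigError("'simulation.initial_state' must be a mapping")
            try:
                sim_d["initial_state"] = SystemState(**st)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"invalid 'simulation.initial_state': {err}") from err
        sim = build("simulation", SimulationSettings, sim_d)
        ana = build("analysis", AnalysisConfig, d.get("analysis", {}))
        temp_d = dict(d.get("temporal", {}))
        if "phase_durations" in temp_d:
            temp_d["phase_durations"] = tuple(temp_d["phase_durations"])
        temp = build("temporal", TemporalConfig, temp_d)
        return cls(params, env, sim, ana, temp)


def dump_config(config: RunConfig) -> str:
    """Serialize to YAML (block style, stable key order)."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a YAML configuration file; missing keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def apply_overrides(config: RunConfig, overrides: Mapping[str, str]) -> RunConfig:
    """Apply dotted-key overrides such as ``parameters.H_O=60``.

    Values are parsed as YAML scalars, so plain numbers, scientific notation
    and booleans all work.
    """
    d = config.to_dict()
    for key, raw in overrides.items():
        parts = key.split(".")
        node: Any = d
        for p in parts[:-1]:
            if not isinstance(node, dict) or p not in node:
                raise ConfigError(f"unknown configuration key: {key!r}")
            node = node[p]
        if not isinstance(node, dict) or parts[-1] not in node:
            raise ConfigError(f"unknown configuration key: {key!r}")
        value = yaml.safe_load(raw)
        if isinstance(value, str):
            # YAML 1.1 does not recognise bare "5e5" as a float
            try:
                value = float(value)
            except ValueError:
                pass
        node[parts[-1]] = value
    return RunConfig.from_dict(d)
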
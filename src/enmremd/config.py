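"""Layered run configuration.

A :class:`RunConfig` carries every knob of the pipeline with the
published protocol constants as defaults: 50 excited modes, 12 replicas,
2 ps exchange period, 0.2 ns control period, 0.4 ns d0 averaging window,
2.25 kcal/mol starting bias level.  All times are in ps, lengths in Å,
energies in kcal/mol, temperatures in K.

``toy_schedule=True`` rescales the exchange, control and averaging times
uniformly 100× down for desk-scale runs on the synthetic fixtures.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "dump_config"]

#: factor by which --toy-schedule compresses all protocol time constants
TOY_TIME_FACTOR = 100.0


@dataclass
class RunConfig:
    # structure source: "fixture" or a PDB file path
    structure: str = "fixture"
    chains: list = field(default_factory=list)      # empty = all chains
    truncation_boundary: int = 0                    # author residue numbering
    # domain ranges: chain -> [[first, last, domain], ...]; empty = fixture's
    domain_ranges: dict = field(default_factory=dict)
    beads_per_domain: int = 20                      # fixture size
    hinge_angle: float = 100.0                      # fixture geometry, degrees
    # elastic network
    enm_rule: str = "hinsen"
    cutoff: float = 10.0                            # Å, for the cutoff rule
    n_modes: int = 50
    # thermodynamics / dynamics
    temperature: float = 300.0                      # K
    dt: float = 0.01                                # ps
    friction: float = 1.0                           # ps^-1
    # replica ladder
    n_replicas: int = 12
    start_level: float = 2.25                       # kcal/mol per replica step
    ladder_spacing: str = "linear"
    d0_mode: str = "shared"                         # or "per_replica"
    controller_mode: str = "per_pair"               # or "global"
    # schedule (ps of simulated time, full-protocol scale)
    n_steps: int = 80_000                           # per replica
    exchange_period: float = 2.0                    # ps
    control_period: float = 200.0                   # ps (0.2 ns)
    d0_window: float = 400.0                        # ps (0.4 ns)
    output_stride: int = 20                         # steps between frames
    toy_schedule: bool = False

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ConfigurationError("n_replicas must be ≥ 2")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.temperature < 0 or self.friction < 0:
            raise ConfigurationError("temperature and friction must be ≥ 0")
        if self.n_modes < 0:
            raise ConfigurationError("n_modes must be ≥ 0")
        if self.start_level < 0:
            raise ConfigurationError("start_level must be ≥ 0")
        if self.enm_rule not in ("hinsen", "cutoff"):
            raise ConfigurationError(f"unknown enm_rule {self.enm_rule!r}")
        if self.d0_mode not in ("shared", "per_replica"):
            raise ConfigurationError(f"unknown d0_mode {self.d0_mode!r}")
        if self.controller_mode not in ("per_pair", "global"):
            raise ConfigurationError(
                f"unknown controller_mode {self.controller_mode!r}"
            )

    # ---- schedule in integrator steps, honoring the toy flag -------------
    def _time_factor(self) -> float:
        return TOY_TIME_FACTOR if self.toy_schedule else 1.0

    def exchange_period_steps(self) -> int:
        return max(int(round(self.exchange_period / self._time_factor() / self.dt)), 1)

    def control_period_steps(self) -> int:
        per = max(int(round(self.control_period / self._time_factor() / self.dt)), 1)
        # align to the exchange grid so controller updates see whole windows
        ex = self.exchange_period_steps()
        return max(per // ex, 1) * ex

    def d0_window_steps(self) -> int:
        return max(int(round(self.d0_window / self._time_factor() / self.dt)), 1)


def _known_keys() -> set:
    return {f.name for f in dataclasses.fields(RunConfig)}


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML file path, file object, or dict.

    Unknown keys are rejected by name; an empty file yields all defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    elif isinstance(source, dict):
        data = dict(source)
    else:
        data = yaml.safe_load(source)
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(data) - _known_keys()
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to YAML (round-trips through load_config)."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False)
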
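"""Validated run configuration with defaults for the canonical network.

Every default reproduces the reference conditions: 40x40 pyramidal and
20x20 inhibitory grids, out-degrees 121/29/49, per-synapse conductance
increments 0.0006/0.0002/0.0004, decay constants 2/3 ms, depression
coefficient 0.6 with 300 ms recovery, dt = 0.1 ms, uniform noise up to
5/2 pA, and 5 pA / 4 Hz stimulation.  Configs load from and save to YAML;
unknown keys are rejected.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigurationError
from .stimulation import NoiseSpec, StimulusProtocol


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NetworkConfig(_Block):
    py_shape: Tuple[int, int] = (40, 40)
    in_shape: Tuple[int, int] = (20, 20)
    degree_py_py: int = 121
    degree_py_in: int = 29
    degree_in_py: int = 49
    radius_py_py: Optional[int] = 6     # None -> minimal covering radius
    radius_py_in: Optional[int] = 3
    w_py_py: float = 0.027
    w_py_in: float = 0.009
    w_in_py: float = 0.018


class NoiseConfig(_Block):
    max_ex: float = 5.0
    max_in: float = 2.0
    interval_ms: float = 10.0
    event_prob: float = 0.15

    @model_validator(mode="after")
    def _valid(self):
        if self.max_ex < 0 or self.max_in < 0:
            raise ValueError("noise maxima must be >= 0 (noise.max_ex / noise.max_in)")
        if self.interval_ms <= 0:
            raise ValueError("noise.interval_ms must be > 0")
        if not 0 <= self.event_prob <= 1:
            raise ValueError("noise.event_prob must be in [0, 1]")
        return self

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(max_ex=self.max_ex, max_in=self.max_in,
                         interval_ms=self.interval_ms, event_prob=self.event_prob)


class StimulusConfig(_Block):
    kind: Literal["none", "tdcs", "tacs"] = "none"
    amplitude: float = 5.0
    frequency: float = 4.0
    phase: float = 0.0
    mode: Literal["full", "depolarizing_only", "hyperpolarizing_only"] = "full"
    onset_ms: float = 0.0
    offset_ms: Optional[float] = None   # None -> until end of run
    target: Literal["all", "excitatory_only"] = "all"

    def to_protocol(self) -> Optional[StimulusProtocol]:
        if self.kind == "none":
            return None
        return StimulusProtocol(
            kind=self.kind,
            amplitude=self.amplitude,
            frequency=self.frequency,
            phase=self.phase,
            mode=self.mode,
            onset_ms=self.onset_ms,
            offset_ms=math.inf if self.offset_ms is None else self.offset_ms,
            target=self.target,
        )


class EngineConfig(_Block):
    dt_ms: float = 0.1
    duration_ms: float = 5000.0
    activity_bin_ms: float = 5.0
    spike_threshold_mv: float = 30.0
    n_trace_ex: int = 3
    n_trace_in: int = 3

    @model_validator(mode="after")
    def _positive(self):
        if self.dt_ms <= 0:
            raise ValueError("engine.dt must be > 0")
        if self.duration_ms <= 0:
            raise ValueError("engine.duration_ms must be > 0")
        if self.activity_bin_ms <= 0:
            raise ValueError("engine.activity_bin_ms must be > 0")
        return self


class SynapseConfig(_Block):
    tau_ex_ms: float = 2.0
    tau_in_ms: float = 3.0
    r_dep: float = 0.6
    tau_dep_ms: float = 300.0


class AnalysisConfig(_Block):
    welch_window_s: float = 1.0
    welch_overlap: float = 0.5
    half_band_hz: float = 0.5
    total_band_hz: Tuple[float, float] = (0.5, 50.0)


class ClosedLoopConfig(_Block):
    window_s: float = 2.0
    step_s: float = 0.5
    band_hz: Tuple[float, float] = (3.0, 10.0)
    significance_sd: float = 3.0
    snr_min: float = 5.0
    min_consistent_windows: int = 3
    agreement_hz: float = 0.5
    amplitude_policy: Literal["fixed", "proportional"] = "fixed"
    amplitude_pa: float = 5.0
    amplitude_gain: float = 0.25   # pA per activity-% unit, proportional policy
    max_monitor_ms: float = 10000.0
    post_onset_ms: float = 5000.0


class RunConfig(_Block):
    """Full configuration of one simulation run."""

    seed: int = 0
    network: NetworkConfig = NetworkConfig()
    noise: NoiseConfig = NoiseConfig()
    stimulus: StimulusConfig = StimulusConfig()
    engine: EngineConfig = EngineConfig()
    synapses: SynapseConfig = SynapseConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    closed_loop: ClosedLoopConfig = ClosedLoopConfig()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def default_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        details = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise ConfigurationError(f"invalid configuration: {details}") from err


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_yaml())
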
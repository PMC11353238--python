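"""Noise and transcranial stimulation current waveforms.

tDCS is a constant current of the given amplitude; tACS is
A sin(2 pi f t / 1000 + phi) with t in ms, optionally half-wave rectified:
``depolarizing_only`` keeps max(0, sine), ``hyperpolarizing_only`` keeps
min(0, sine) (the two rectified waveforms partition the full sine exactly).
Background noise is an independent per-neuron, per-step uniform draw on
[0, 5] pA for excitatory and [0, 2] pA for inhibitory neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

KIND_NONE = "none"
KIND_TDCS = "tdcs"
KIND_TACS = "tacs"

MODE_FULL = "full"
MODE_DEPOL = "depolarizing_only"
MODE_HYPER = "hyperpolarizing_only"

TARGET_ALL = "all"
TARGET_EXC = "excitatory_only"


@dataclass(frozen=True)
class StimulusProtocol:
    """One stimulation epoch: waveform kind, parameters and time span."""

    kind: str = KIND_NONE
    amplitude: float = 0.0        # pA
    frequency: float = 0.0        # Hz (tACS only)
    phase: float = 0.0            # radians
    mode: str = MODE_FULL
    onset_ms: float = 0.0
    offset_ms: float = math.inf
    target: str = TARGET_ALL

    def __post_init__(self):
        if self.kind not in (KIND_NONE, KIND_TDCS, KIND_TACS):
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if self.mode not in (MODE_FULL, MODE_DEPOL, MODE_HYPER):
            raise ConfigurationError(f"unknown stimulus mode {self.mode!r}")
        if self.target not in (TARGET_ALL, TARGET_EXC):
            raise ConfigurationError(f"unknown stimulus target {self.target!r}")
        if self.amplitude < 0:
            raise ConfigurationError("stimulus amplitude must be >= 0")
        if self.offset_ms <= self.onset_ms:
            raise ConfigurationError("stimulus offset must exceed onset")
        if self.kind == KIND_TACS and self.frequency <= 0:
            raise ConfigurationError("tACS requires frequency > 0")
        if self.mode != MODE_FULL and self.kind != KIND_TACS:
            raise ConfigurationError("half-wave modes apply to tACS only")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise process parameters.

    Noise emulates afferent background input as brief current kicks: each
    neuron's noise is piecewise constant over independent (staggered)
    intervals of ``interval_ms``; at each interval boundary the neuron
    draws, with probability ``event_prob``, a current uniform on
    [0, max] pA (``max_ex`` excitatory, ``max_in`` inhibitory) held for the
    interval, and is otherwise noise-free.  ``event_prob = 1`` reduces to a
    continuously redrawn uniform current.
    """

    max_ex: float = 5.0
    max_in: float = 2.0
    interval_ms: float = 10.0
    event_prob: float = 0.15


def stimulus_value(proto: StimulusProtocol, t: float | np.ndarray) -> float | np.ndarray:
    """Injected current (pA) of ``proto`` at time ``t`` (ms); vectorized in t."""
    t = np.asarray(t, dtype=float)
    active = (t >= proto.onset_ms) & (t < proto.offset_ms)
    if proto.kind == KIND_NONE:
        out = np.zeros_like(t)
    elif proto.kind == KIND_TDCS:
        out = np.where(active, proto.amplitude, 0.0)
    else:
        wave = proto.amplitude * np.sin(
            2.0 * np.pi * proto.frequency * t / 1000.0 + proto.phase
        )
        if proto.mode == MODE_DEPOL:
            wave = np.maximum(wave, 0.0)
        elif proto.mode == MODE_HYPER:
            wave = np.minimum(wave, 0.0)
        out = np.where(active, wave, 0.0)
    return out if out.ndim else float(out)


def noise_draw(
    spec: NoiseSpec,
    n_ex: int,
    n_in: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent per-neuron Uniform[0, max] noise currents (one draw)."""
    return (
        rng.uniform(0.0, spec.max_ex, size=n_ex),
        rng.uniform(0.0, spec.max_in, size=n_in),
    )


class NoiseProcess:
    """Stateful per-neuron kick-noise process (see NoiseSpec).

    Interval boundaries are staggered uniformly across neurons so the
    population receives no common refresh clock.
    """

    def __init__(self, spec: NoiseSpec, n_ex: int, n_in: int, dt_ms: float,
                 rng: np.random.Generator):
        self.spec = spec
        self.dt = dt_ms
        self.rng = rng
        self.hold_steps = max(1, int(round(spec.interval_ms / dt_ms)))
        self._count_ex = rng.integers(1, self.hold_steps + 1, size=n_ex)
        self._count_in = rng.integers(1, self.hold_steps + 1, size=n_in)
        self._cur_ex = np.zeros(n_ex)
        self._cur_in = np.zeros(n_in)
        self._refresh(np.ones(n_ex, bool), np.ones(n_in, bool))

    def _refresh(self, mask_ex: np.ndarray, mask_in: np.ndarray) -> None:
        spec, rng = self.spec, self.rng
        for mask, cur, hi in (
            (mask_ex, self._cur_ex, spec.max_ex),
            (mask_in, self._cur_in, spec.max_in),
        ):
            k = int(mask.sum())
            if k == 0:
                continue
            on = rng.uniform(size=k) < spec.event_prob
            vals = np.where(on, rng.uniform(0.0, hi, size=k), 0.0)
            cur[mask] = vals

    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """Noise currents for the current step; advances the process."""
        ex_due = self._count_ex <= 0
        in_due = self._count_in <= 0
        if ex_due.any() or in_due.any():
            self._refresh(ex_due, in_due)
            self._count_ex[ex_due] = self.hold_steps
            self._count_in[in_due] = self.hold_steps
        self._count_ex -= 1
        self._count_in -= 1
        return self._cur_ex, self._cur_in
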
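"""Per-step orchestration of the network simulation.

Update order within a step of length dt (default 0.1 ms):

1. decay conductances;
2. assemble I_total = noise + stimulus + synaptic current;
3. forward-Euler membrane update;
4. spike detection and reset;
5. instantaneous spike delivery into postsynaptic conductances;
6. depression recovery and per-spike depression;
7. recording (raster, sampled traces, delivered stimulus).

The excitatory and inhibitory population-activity signals are the
percentage of distinct neurons of a population that spike within each
activity bin (default 5 ms), i.e. a rate signal sampled at 1000/bin Hz;
all spectral analyses consume this signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig, default_config
from .errors import NumericError
from .neurons import (
    EXCITATORY,
    INHIBITORY,
    NeuronPopulation,
    detect_and_reset,
    make_population,
    membrane_step,
)
from .stimulation import (
    TARGET_ALL,
    NoiseProcess,
    StimulusProtocol,
    stimulus_value,
)
from .synapses import (
    SynapseState,
    decay_conductances,
    deliver_spikes,
    make_synapse_state,
    synaptic_current,
    update_depression,
)
from .topology import SynapticNetwork, build_network


@dataclass
class SimulationResult:
    """Raster, traces, activity signals and provenance of one run."""

    dt_ms: float
    duration_ms: float
    spike_times_ex: np.ndarray
    spike_ids_ex: np.ndarray
    spike_times_in: np.ndarray
    spike_ids_in: np.ndarray
    n_ex: int
    n_in: int
    activity_bin_ms: float
    trace_ids_ex: np.ndarray
    trace_ids_in: np.ndarray
    traces_ex: np.ndarray          # (n_steps, n_trace_ex) membrane voltages
    traces_in: np.ndarray
    stimulus_log: np.ndarray       # delivered current at every step
    seed: int
    config: RunConfig
    _activity: dict = field(default_factory=dict, repr=False)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt_ms))

    @property
    def activity_fs_hz(self) -> float:
        return 1000.0 / self.activity_bin_ms

    def activity(self, population: str, bin_ms: Optional[float] = None) -> np.ndarray:
        """Percentage-of-spiking-neurons series for one population."""
        bin_ms = self.activity_bin_ms if bin_ms is None else bin_ms
        key = (population, bin_ms)
        if key not in self._activity:
            if population == EXCITATORY:
                times, ids, n = self.spike_times_ex, self.spike_ids_ex, self.n_ex
            elif population == INHIBITORY:
                times, ids, n = self.spike_times_in, self.spike_ids_in, self.n_in
            else:
                raise ValueError(f"unknown population {population!r}")
            self._activity[key] = population_activity(
                times, ids, n, bin_ms, self.duration_ms
            )
        return self._activity[key]

    @property
    def activity_ex(self) -> np.ndarray:
        return self.activity(EXCITATORY)

    @property
    def activity_in(self) -> np.ndarray:
        return self.activity(INHIBITORY)


def population_activity(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    n: int,
    bin_ms: float,
    duration_ms: float,
) -> np.ndarray:
    """Per-bin percentage of distinct neurons with at least one spike.

    A neuron spiking several times within one bin is counted once.  An empty
    raster yields an all-zero series.
    """
    n_bins = int(np.ceil(duration_ms / bin_ms))
    if len(spike_times) == 0:
        return np.zeros(n_bins)
    bins = np.minimum((np.asarray(spike_times) / bin_ms).astype(int), n_bins - 1)
    pair = np.unique(bins.astype(np.int64) * n + np.asarray(spike_ids))
    counts = np.bincount((pair // n).astype(int), minlength=n_bins)
    return 100.0 * counts / n


class Simulation:
    """Incremental simulator; supports mid-run protocol changes (closed loop)."""

    def __init__(self, config: Optional[RunConfig] = None,
                 protocol: Optional[StimulusProtocol] = None,
                 network: Optional[SynapticNetwork] = None):
        self.config = config or default_config()
        cfg = self.config
        self.rng = np.random.default_rng(cfg.seed)
        net_cfg = cfg.network
        self.network = network if network is not None else build_network(
            self.rng,
            py_shape=tuple(net_cfg.py_shape),
            in_shape=tuple(net_cfg.in_shape),
            degrees=(net_cfg.degree_py_py, net_cfg.degree_py_in, net_cfg.degree_in_py),
            weights=(net_cfg.w_py_py, net_cfg.w_py_in, net_cfg.w_in_py),
            radii=None
            if net_cfg.radius_py_py is None or net_cfg.radius_py_in is None
            else (net_cfg.radius_py_py, net_cfg.radius_py_in),
        )
        n_py, n_in = self.network.n_py, self.network.n_in
        self.pop_ex = make_population(EXCITATORY, n_py, self.network.py_shape, self.rng)
        self.pop_in = make_population(INHIBITORY, n_in, self.network.in_shape, self.rng)
        self.state: SynapseState = make_synapse_state(
            n_py, n_in,
            r_dep=cfg.synapses.r_dep, tau_dep=cfg.synapses.tau_dep_ms,
        )
        self.state.tau_ex = cfg.synapses.tau_ex_ms
        self.state.tau_in = cfg.synapses.tau_in_ms
        self.noise = NoiseProcess(
            cfg.noise.to_spec(), n_py, n_in, cfg.engine.dt_ms, self.rng
        )
        self.protocol = protocol
        self.dt = cfg.engine.dt_ms
        self.threshold = cfg.engine.spike_threshold_mv
        self.step_idx = 0
        self.trace_ids_ex = np.linspace(
            0, n_py - 1, cfg.engine.n_trace_ex, dtype=int
        ) if cfg.engine.n_trace_ex else np.empty(0, dtype=int)
        self.trace_ids_in = np.linspace(
            0, n_in - 1, cfg.engine.n_trace_in, dtype=int
        ) if cfg.engine.n_trace_in else np.empty(0, dtype=int)
        self._spike_t_ex: list = []
        self._spike_i_ex: list = []
        self._spike_t_in: list = []
        self._spike_i_in: list = []
        self._traces_ex: list = []
        self._traces_in: list = []
        self._stim_log: list = []

    @property
    def t_ms(self) -> float:
        return self.step_idx * self.dt

    def set_protocol(self, protocol: Optional[StimulusProtocol]) -> None:
        self.protocol = protocol

    def step(self) -> None:
        t = self.t_ms
        net, state = self.network, self.state
        pe, pi = self.pop_ex, self.pop_in

        decay_conductances(state, self.dt)

        noise_ex, noise_in = self.noise.step()
        stim = 0.0
        if self.protocol is not None:
            stim = stimulus_value(self.protocol, t)
        i_ex = noise_ex + synaptic_current(
            state.g_ex_py, state.g_in_py, pe.V, state.v_ampa, state.v_gaba
        )
        i_in = noise_in + synaptic_current(
            state.g_ex_in, 0.0, pi.V, state.v_ampa, state.v_gaba
        )
        if stim != 0.0:
            i_ex = i_ex + stim
            if self.protocol.target == TARGET_ALL:
                i_in = i_in + stim

        membrane_step(pe, i_ex, self.dt)
        membrane_step(pi, i_in, self.dt)
        mask_ex = detect_and_reset(pe, self.threshold)
        mask_in = detect_and_reset(pi, self.threshold)

        if mask_ex.any():
            ids = np.flatnonzero(mask_ex)
            self._spike_i_ex.append(ids)
            self._spike_t_ex.append(np.full(len(ids), t))
        if mask_in.any():
            ids = np.flatnonzero(mask_in)
            self._spike_i_in.append(ids)
            self._spike_t_in.append(np.full(len(ids), t))

        deliver_spikes(net, state, mask_ex, mask_in)
        update_depression(state, mask_ex, self.dt)

        if len(self.trace_ids_ex):
            self._traces_ex.append(pe.V[self.trace_ids_ex].copy())
        if len(self.trace_ids_in):
            self._traces_in.append(pi.V[self.trace_ids_in].copy())
        self._stim_log.append(stim)

        if not np.isfinite(pe.V).all() or not np.isfinite(pi.V).all():
            raise NumericError(f"non-finite state after step {self.step_idx}")
        self.step_idx += 1

    def run(self, until_ms: Optional[float] = None) -> None:
        """Advance until simulated time reaches ``until_ms`` (config duration
        by default)."""
        target = self.config.engine.duration_ms if until_ms is None else until_ms
        n_target = int(round(target / self.dt))
        while self.step_idx < n_target:
            self.step()

    def result(self) -> SimulationResult:
        def cat(parts, dtype=float):
            return (
                np.concatenate(parts).astype(dtype)
                if parts else np.empty(0, dtype=dtype)
            )

        return SimulationResult(
            dt_ms=self.dt,
            duration_ms=self.t_ms,
            spike_times_ex=cat(self._spike_t_ex),
            spike_ids_ex=cat(self._spike_i_ex, int),
            spike_times_in=cat(self._spike_t_in),
            spike_ids_in=cat(self._spike_i_in, int),
            n_ex=self.pop_ex.n,
            n_in=self.pop_in.n,
            activity_bin_ms=self.config.engine.activity_bin_ms,
            trace_ids_ex=self.trace_ids_ex,
            trace_ids_in=self.trace_ids_in,
            traces_ex=np.array(self._traces_ex) if self._traces_ex else np.empty((0, 0)),
            traces_in=np.array(self._traces_in) if self._traces_in else np.empty((0, 0)),
            stimulus_log=np.asarray(self._stim_log),
            seed=self.config.seed,
            config=self.config,
        )


def run_simulation(
    config: Optional[RunConfig] = None,
    protocol: Optional[StimulusProtocol] = None,
    network: Optional[SynapticNetwork] = None,
) -> SimulationResult:
    """Run a complete simulation of ``config.engine.duration_ms``.

    When ``protocol`` is omitted it is taken from the config's stimulus
    block ("none" means unstimulated).
    """
    config = config or default_config()
    if protocol is None:
        protocol = config.stimulus.to_protocol()
    sim = Simulation(config, protocol=protocol, network=network)
    sim.run()
    return sim.result()
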
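"""Conductance dynamics: exponential decay, spike delivery, short-term depression.

Per-neuron summed conductances decay exponentially (tau_EX = 2 ms,
tau_IN = 3 ms).  A presynaptic spike increments the conductance of every
postsynaptic target by the projection weight; pyramidal-to-pyramidal
increments are scaled by the presynaptic depression variable d_dep in (0, 1]
(g = d * G).  After each spike d_dep is multiplied by r = 0.6 and recovers
exponentially toward 1 with time constant tau_d = 300 ms.

Synaptic current into a neuron at potential V is
    I_syn = -G_EX (V - V_AMPA) - G_IN (V - V_GABA)
with reversal potentials V_AMPA = 0 mV and V_GABA = -80 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import SynapticNetwork

TAU_EX_MS = 2.0
TAU_IN_MS = 3.0
R_DEP = 0.6
TAU_DEP_MS = 300.0
V_AMPA_MV = 0.0
V_GABA_MV = -80.0


@dataclass
class SynapseState:
    """Summed conductances per neuron and per-PY depression variables."""

    g_ex_py: np.ndarray  # excitatory conductance onto each PY neuron
    g_in_py: np.ndarray  # inhibitory conductance onto each PY neuron
    g_ex_in: np.ndarray  # excitatory conductance onto each IN neuron
    d_dep: np.ndarray    # depression variable of each PY neuron, in (0, 1]
    tau_ex: float = TAU_EX_MS
    tau_in: float = TAU_IN_MS
    r_dep: float = R_DEP
    tau_dep: float = TAU_DEP_MS
    v_ampa: float = V_AMPA_MV
    v_gaba: float = V_GABA_MV


def make_synapse_state(
    n_py: int,
    n_in: int,
    r_dep: float = R_DEP,
    tau_dep: float = TAU_DEP_MS,
) -> SynapseState:
    """Fresh state: all conductances zero, depression fully recovered."""
    return SynapseState(
        g_ex_py=np.zeros(n_py),
        g_in_py=np.zeros(n_py),
        g_ex_in=np.zeros(n_in),
        d_dep=np.ones(n_py),
        r_dep=r_dep,
        tau_dep=tau_dep,
    )


def decay_conductances(state: SynapseState, dt: float) -> None:
    """Exponential decay G <- G exp(-dt/tau), elementwise and in place."""
    fe = np.exp(-dt / state.tau_ex)
    fi = np.exp(-dt / state.tau_in)
    state.g_ex_py *= fe
    state.g_ex_in *= fe
    state.g_in_py *= fi


def deliver_spikes(
    net: SynapticNetwork,
    state: SynapseState,
    spikes_ex: np.ndarray,
    spikes_in: np.ndarray,
) -> None:
    """Add this step's presynaptic spikes into postsynaptic conductances.

    PY->PY increments are w_py_py scaled by the presynaptic d_dep; PY->IN
    increments are the undepressed w_py_in; IN->PY increments are w_in_py.
    Delivery is instantaneous (no conduction delay).
    """
    m_pp, m_pi, m_ip = net.delivery_matrices()
    if spikes_ex.any():
        drive = np.where(spikes_ex, state.d_dep, 0.0)
        state.g_ex_py += net.w_py_py * (m_pp @ drive)
        state.g_ex_in += net.w_py_in * (m_pi @ spikes_ex.astype(float))
    if spikes_in.any():
        state.g_in_py += net.w_in_py * (m_ip @ spikes_in.astype(float))


def update_depression(state: SynapseState, spikes_ex: np.ndarray, dt: float) -> None:
    """Recover d_dep toward 1 over dt, then depress this step's spikers.

    Recovery is exponential with time constant tau_dep; each spiking
    pyramidal neuron's d_dep is then multiplied by r_dep.
    """
    state.d_dep[:] = 1.0 - (1.0 - state.d_dep) * np.exp(-dt / state.tau_dep)
    if spikes_ex.any():
        state.d_dep[spikes_ex] *= state.r_dep


def synaptic_current(
    g_ex: np.ndarray,
    g_in: np.ndarray,
    V: np.ndarray,
    v_ampa: float = V_AMPA_MV,
    v_gaba: float = V_GABA_MV,
) -> np.ndarray:
    """Total synaptic current -G_EX (V - V_AMPA) - G_IN (V - V_GABA)."""
    return -g_ex * (V - v_ampa) - g_in * (V - v_gaba)
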
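"""Izhikevich membrane dynamics for excitatory and inhibitory populations.

Each neuron is a two-variable quadratic integrate-and-fire unit: membrane
potential ``V`` (mV) with dV/dt = 0.04 V^2 + 5 V + 140 - u + I, and a slow
recovery variable ``u`` with du/dt = a (b V - u).  When V crosses +30 mV the
neuron spikes: V is reset to ``c`` and u is incremented by ``d_reset``.

Parameter heterogeneity follows the canonical cortical-network convention:
regular-spiking excitatory cells share a = 0.02, b = 0.2 and draw
c = -65 + 15 rho^2 in [-65, -50] mV and d_reset = 8 - 6 rho^2 in [2, 8]
(the squared deviate biases the population toward regular spiking);
fast-spiking inhibitory cells share c = -65, d_reset = 2 and draw
a = 0.02 + 0.08 rho in [0.02, 0.1], b = 0.25 - 0.05 rho in [0.2, 0.25].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NumericError

SPIKE_THRESHOLD_MV = 30.0
V_INIT_MV = -65.0

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass
class NeuronPopulation:
    """State and parameters of one homogeneous-kind population.

    All per-neuron quantities are float64 arrays of length ``n`` laid out in
    row-major order over ``grid_shape``.
    """

    kind: str
    n: int
    grid_shape: tuple[int, int]
    V: np.ndarray
    u: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d_reset: np.ndarray
    rho: np.ndarray = field(repr=False, default=None)

    def grid_index(self, row: int, col: int) -> int:
        return row * self.grid_shape[1] + col


def make_population(
    kind: str,
    n: int,
    grid_shape: tuple[int, int],
    rng: np.random.Generator,
) -> NeuronPopulation:
    """Create a population with heterogeneous parameters drawn from ``rng``.

    One uniform deviate per neuron drives all of its heterogeneous
    parameters, so excitatory c and d_reset (and inhibitory a and b) are
    perfectly anticorrelated across the population, as in the source model
    family.
    """
    rows, cols = grid_shape
    if n != rows * cols:
        raise ConfigurationError(
            f"population size {n} does not match grid {rows}x{cols}"
        )
    rho = rng.uniform(size=n)
    if kind == EXCITATORY:
        a = np.full(n, 0.02)
        b = np.full(n, 0.2)
        c = -65.0 + 15.0 * rho**2
        d_reset = 8.0 - 6.0 * rho**2
    elif kind == INHIBITORY:
        a = 0.02 + 0.08 * rho
        b = 0.25 - 0.05 * rho
        c = np.full(n, -65.0)
        d_reset = np.full(n, 2.0)
    else:
        raise ConfigurationError(f"unknown population kind {kind!r}")
    V = np.full(n, V_INIT_MV)
    u = b * V
    return NeuronPopulation(
        kind=kind, n=n, grid_shape=(rows, cols),
        V=V, u=u, a=a, b=b, c=c, d_reset=d_reset, rho=rho,
    )


def membrane_step(pop: NeuronPopulation, I_total: np.ndarray | float, dt: float) -> None:
    """Advance (V, u) by one forward-Euler step of length ``dt`` ms.

    ``I_total`` must already contain every current source (noise, stimulus,
    synaptic).  Updates the population in place.
    """
    V, u = pop.V, pop.u
    if not np.isfinite(V).all() or not np.isfinite(u).all():
        bad = int(np.flatnonzero(~(np.isfinite(V) & np.isfinite(u)))[0])
        raise NumericError(f"non-finite membrane state at neuron {bad}")
    dV = 0.04 * V * V + 5.0 * V + 140.0 - u + I_total
    du = pop.a * (pop.b * V - u)
    V += dt * dV
    u += dt * du


def detect_and_reset(
    pop: NeuronPopulation, threshold: float = SPIKE_THRESHOLD_MV
) -> np.ndarray:
    """Spike detection and post-spike reset.

    Returns the boolean mask of neurons with V >= threshold; those neurons
    have V set to their reset potential c and u incremented by d_reset.
    """
    mask = pop.V >= threshold
    if mask.any():
        pop.V[mask] = pop.c[mask]
        pop.u[mask] += pop.d_reset[mask]
    return mask
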
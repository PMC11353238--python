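"""Construction of the three-projection network on the two 2-D grids.

The default network places 1600 pyramidal (PY) neurons on a 40x40 grid and
400 inhibitory (IN) neurons on a 20x20 grid.  Connectivity is fixed
out-degree:

* PY->PY: each pyramidal neuron contacts exactly 121 distinct pyramidal
  targets sampled without replacement from its Chebyshev radius-6
  neighbourhood (pool 168 for interior neurons; clipped at the edges, no
  wraparound).
* PY->IN: the PY grid position (i, j) maps onto the coarser IN grid at
  (i//2, j//2); 29 IN targets are sampled from the radius-3 neighbourhood of
  that position (pool 49 interior).
* IN->PY: each inhibitory neuron contacts exactly 49 pyramidal neurons
  sampled uniformly from the whole PY population (global negative feedback).

Radii are the smallest Chebyshev radii whose interior pools cover the
requested degrees; edge neurons receive min(degree, pool) targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError

DEFAULT_PY_SHAPE = (40, 40)
DEFAULT_IN_SHAPE = (20, 20)
DEFAULT_DEGREES = (121, 29, 49)  # PY->PY, PY->IN, IN->PY
# Per-synapse conductance increments in the 6:2:4 ratio of the reference
# parameter set, scaled by a common factor (x45) calibrated so excitation
# waves propagate through resting tissue and the depression-paced slow
# rhythm emerges (see docs/methods.md).
DEFAULT_WEIGHTS = (0.027, 0.009, 0.018)
DEFAULT_RADII = (6, 3)  # PY->PY, PY->IN Chebyshev radii


@dataclass
class SynapticNetwork:
    """Adjacency of the three projections plus per-projection weights.

    ``py_py[i]`` is the integer array of pyramidal targets of pyramidal
    neuron ``i`` (likewise ``py_in`` and ``in_py``).  Cached CSR matrices
    (post x pre, unit entries) implement one-step spike delivery as a
    sparse matrix-vector product.
    """

    py_shape: tuple[int, int]
    in_shape: tuple[int, int]
    py_py: list[np.ndarray]
    py_in: list[np.ndarray]
    in_py: list[np.ndarray]
    w_py_py: float = DEFAULT_WEIGHTS[0]
    w_py_in: float = DEFAULT_WEIGHTS[1]
    w_in_py: float = DEFAULT_WEIGHTS[2]
    _m_py_py: sp.csr_matrix = field(default=None, repr=False)
    _m_py_in: sp.csr_matrix = field(default=None, repr=False)
    _m_in_py: sp.csr_matrix = field(default=None, repr=False)

    @property
    def n_py(self) -> int:
        return self.py_shape[0] * self.py_shape[1]

    @property
    def n_in(self) -> int:
        return self.in_shape[0] * self.in_shape[1]

    def py_coords(self) -> np.ndarray:
        return _grid_coords(self.py_shape)

    def in_coords(self) -> np.ndarray:
        return _grid_coords(self.in_shape)

    def delivery_matrices(self) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        """CSR matrices (post x pre) for PY->PY, PY->IN and IN->PY."""
        if self._m_py_py is None:
            self._m_py_py = _adjacency_matrix(self.py_py, self.n_py)
            self._m_py_in = _adjacency_matrix(self.py_in, self.n_in)
            self._m_in_py = _adjacency_matrix(self.in_py, self.n_py)
        return self._m_py_py, self._m_py_in, self._m_in_py

    def out_degree(self, projection: str, pre_id: int) -> int:
        return len(getattr(self, projection)[pre_id])


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r, c = np.divmod(np.arange(rows * cols), cols)
    return np.column_stack([r, c])


def _adjacency_matrix(adj: list[np.ndarray], n_post: int) -> sp.csr_matrix:
    pre = np.repeat(np.arange(len(adj)), [len(t) for t in adj])
    post = np.concatenate(adj) if adj else np.empty(0, dtype=int)
    m = sp.coo_matrix(
        (np.ones(len(post)), (post, pre)), shape=(n_post, len(adj))
    )
    return m.tocsr()


def chebyshev_neighborhood(
    shape: tuple[int, int], row: int, col: int, radius: int,
    exclude_center: bool,
) -> np.ndarray:
    """Flat indices within Chebyshev ``radius`` of (row, col), edge-clipped."""
    rows, cols = shape
    r0, r1 = max(0, row - radius), min(rows - 1, row + radius)
    c0, c1 = max(0, col - radius), min(cols - 1, col + radius)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    idx = (rr * cols + cc).ravel()
    if exclude_center:
        idx = idx[idx != row * cols + col]
    return idx


def minimal_radius(degree: int, exclude_center: bool) -> int:
    """Smallest Chebyshev radius whose full (interior) pool covers ``degree``."""
    r = 1
    while (2 * r + 1) ** 2 - int(exclude_center) < degree:
        r += 1
    return r


def build_network(
    rng: np.random.Generator,
    py_shape: tuple[int, int] = DEFAULT_PY_SHAPE,
    in_shape: tuple[int, int] = DEFAULT_IN_SHAPE,
    degrees: tuple[int, int, int] = DEFAULT_DEGREES,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    radii: tuple[int, int] | None = DEFAULT_RADII,
) -> SynapticNetwork:
    """Sample the fixed-out-degree network.

    ``degrees`` = (PY->PY, PY->IN, IN->PY) out-degrees; ``radii`` the
    Chebyshev neighbourhood radii of the two local projections (derived as
    the minimal covering radii when None).  Raises ConfigurationError when a
    degree cannot be met even by an interior neuron's pool.
    """
    k_pp, k_pi, k_ip = degrees
    n_py = py_shape[0] * py_shape[1]
    n_in = in_shape[0] * in_shape[1]
    if radii is None:
        radii = (minimal_radius(k_pp, True), minimal_radius(k_pi, False))
    r_pp, r_pi = radii
    interior_pp = (2 * r_pp + 1) ** 2 - 1
    interior_pi = (2 * r_pi + 1) ** 2
    if k_pp > min(interior_pp, n_py - 1):
        raise ConfigurationError(
            f"PY->PY degree {k_pp} exceeds radius-{r_pp} pool {interior_pp}"
        )
    if k_pi > min(interior_pi, n_in):
        raise ConfigurationError(
            f"PY->IN degree {k_pi} exceeds radius-{r_pi} pool {interior_pi}"
        )
    if k_ip > n_py:
        raise ConfigurationError(f"IN->PY degree {k_ip} exceeds PY population {n_py}")

    py_py: list[np.ndarray] = []
    py_in: list[np.ndarray] = []
    in_scale = max(1, round(py_shape[0] / in_shape[0]))
    for pre in range(n_py):
        i, j = divmod(pre, py_shape[1])
        pool = chebyshev_neighborhood(py_shape, i, j, r_pp, exclude_center=True)
        py_py.append(np.sort(rng.choice(pool, size=min(k_pp, len(pool)), replace=False)))
        mi = min(i // in_scale, in_shape[0] - 1)
        mj = min(j // in_scale, in_shape[1] - 1)
        pool_in = chebyshev_neighborhood(in_shape, mi, mj, r_pi, exclude_center=False)
        py_in.append(
            np.sort(rng.choice(pool_in, size=min(k_pi, len(pool_in)), replace=False))
        )
    in_py = [
        np.sort(rng.choice(n_py, size=k_ip, replace=False)) for _ in range(n_in)
    ]
    return SynapticNetwork(
        py_shape=py_shape, in_shape=in_shape,
        py_py=py_py, py_in=py_in, in_py=in_py,
        w_py_py=weights[0], w_py_in=weights[1], w_in_py=weights[2],
    )


def make_toy_network(
    py_shape: tuple[int, int],
    in_shape: tuple[int, int],
    degrees: tuple[int, int, int],
    rng: np.random.Generator,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> SynapticNetwork:
    """Miniature network obeying the same construction contract.

    Radii are derived as the minimal Chebyshev radii covering the requested
    degrees, so invariants (exact interior out-degrees, locality, no self
    connections) hold at any scale.  Intended for fast engine tests.
    """
    return build_network(
        rng, py_shape=py_shape, in_shape=in_shape,
        degrees=degrees, weights=weights, radii=None,
    )
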
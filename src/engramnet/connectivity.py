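"""Wiring of the memory network.

Recurrent wiring: every memory neuron sits on a square grid with torus-like
periodic boundaries and connects to every neuron within Euclidean distance
``radius`` (self-connections excluded); the matrix is symmetric by
construction.  Feed-forward wiring: every memory neuron receives a fixed
number of synapses from input neurons drawn uniformly without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Connectivity",
    "build_recurrent_connectivity",
    "build_feedforward_connectivity",
    "torus_disk",
]


@dataclass
class Connectivity:
    """Binary wiring of the memory area.

    c_rec is held as a boolean CSR matrix (48/900 density at radius 4);
    c_ff as a dense boolean (nM, nI) array.
    """

    c_rec: sp.csr_matrix
    c_ff: np.ndarray
    grid_shape: tuple[int, int]

    @property
    def nM(self) -> int:
        return self.c_ff.shape[0]

    @property
    def nI(self) -> int:
        return self.c_ff.shape[1]

    @cached_property
    def rec_rows(self) -> np.ndarray:
        """Row index of every existing recurrent connection (CSR data order)."""
        return np.repeat(
            np.arange(self.c_rec.shape[0]), np.diff(self.c_rec.indptr)
        )

    @cached_property
    def rec_cols(self) -> np.ndarray:
        return self.c_rec.indices

    def rec_dense(self) -> np.ndarray:
        return self.c_rec.toarray().astype(bool)


def _torus_offsets(radius: float) -> np.ndarray:
    """Lattice offsets (dr, dc) with 0 < dr^2 + dc^2 <= radius^2."""
    r = int(np.floor(radius))
    out = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            d2 = dr * dr + dc * dc
            if 0 < d2 <= radius * radius:
                out.append((dr, dc))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def torus_disk(center: int, radius: float, grid_shape: tuple[int, int]) -> np.ndarray:
    """Indices of neurons within Euclidean torus distance ``radius`` of
    ``center`` (center included): the circular region used for local
    manipulations."""
    rows, cols = grid_shape
    cr, cc = divmod(center, cols)
    members = [center]
    for dr, dc in _torus_offsets(radius):
        members.append(((cr + dr) % rows) * cols + (cc + dc) % cols)
    return np.unique(np.asarray(members, dtype=int))


def build_recurrent_connectivity(
    grid_shape: tuple[int, int] = (30, 30), radius: float = 4.0
) -> sp.csr_matrix:
    """Symmetric torus neighborhood wiring.

    Neuron i connects to j iff their Euclidean distance on the periodic grid
    lies in (0, radius].  Distances are measured with per-axis wraparound
    (minimum-image convention).
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid dimensions must be positive, got {grid_shape}")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius > 0 and (rows < 2 * radius + 1 or cols < 2 * radius + 1):
        raise ValueError(
            f"grid {grid_shape} too small for radius {radius} "
            "(needs >= 2*radius+1 per axis to avoid duplicate wrapping)"
        )
    n = rows * cols
    offsets = _torus_offsets(radius)
    if offsets.size == 0:
        return sp.csr_matrix((n, n), dtype=bool)
    rr, cc = np.divmod(np.arange(n), cols)
    src = np.repeat(np.arange(n), len(offsets))
    dst_r = (rr[:, None] + offsets[:, 0]) % rows
    dst_c = (cc[:, None] + offsets[:, 1]) % cols
    dst = (dst_r * cols + dst_c).ravel()
    m = sp.csr_matrix(
        (np.ones(src.size, dtype=bool), (src, dst)), shape=(n, n)
    )
    return m


def build_feedforward_connectivity(
    nM: int, nI: int, fanin: int, rng: np.random.Generator
) -> np.ndarray:
    """Each memory neuron receives exactly ``fanin`` distinct inputs, chosen
    uniformly and independently per neuron."""
    if not (1 <= fanin <= nI):
        raise ValueError(f"fanin must lie in [1, nI={nI}], got {fanin}")
    c = np.zeros((nM, nI), dtype=bool)
    for i in range(nM):
        c[i, rng.choice(nI, size=fanin, replace=False)] = True
    return c


def build_connectivity(params, rng: np.random.Generator) -> Connectivity:
    """Build the full wiring from model parameters and a seeded generator."""
    return Connectivity(
        c_rec=build_recurrent_connectivity(params.grid_shape, params.radius),
        c_ff=build_feedforward_connectivity(params.nM, params.nI, params.fanin, rng),
        grid_shape=tuple(params.grid_shape),
    )
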
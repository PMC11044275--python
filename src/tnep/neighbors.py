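"""Neighbor enumeration for finite and periodic systems.

Periodic images are found by explicit replication: the number of image
shells per lattice direction is chosen from the distance between lattice
planes so that every image within the cutoff is visited, which keeps
strongly skewed cells safe (no fractional-coordinate rounding).  A neighbor
may therefore appear once per image; self pairs (i, i) occur only through
nonzero image shifts and always have d > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AtomicStructure


@dataclass
class NeighborTable:
    """Ordered pairs (i, j) with displacement r_ij = r_j - r_i (+ image shift).

    Arrays are aligned: pair p connects ``i_idx[p]`` to ``j_idx[p]`` through
    image shift ``shift[p]`` (integer lattice multiples) with displacement
    ``r_ij[p]`` (Angstrom) and distance ``d[p]`` < cutoff.  Ordering is
    deterministic: ascending i, then j, then lexicographic shift.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray
    shift: np.ndarray
    r_ij: np.ndarray
    d: np.ndarray
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return len(self.i_idx)

    def neighbors_of(self, i: int):
        """Indices into the pair arrays of all pairs originating at atom i."""
        return np.nonzero(self.i_idx == i)[0]


def _plane_distances(cell: np.ndarray) -> np.ndarray:
    """Distance between lattice planes along each cell vector."""
    vol = abs(np.linalg.det(cell))
    out = np.empty(3)
    for k in range(3):
        a, b = cell[(k + 1) % 3], cell[(k + 2) % 3]
        out[k] = vol / np.linalg.norm(np.cross(a, b))
    return out


def build_neighbor_table(structure: AtomicStructure, cutoff: float) -> NeighborTable:
    """Enumerate all ordered pairs with d_ij < cutoff.

    For periodic directions enough image shells are replicated to cover the
    cutoff; finite directions get no images.  Ties at exactly the cutoff are
    excluded (the smooth cutoff function vanishes there anyway).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = structure.positions
    n = structure.n_atoms
    if any(structure.pbc):
        cell = structure.cell
        if abs(np.linalg.det(cell)) < 1e-12:
            raise ValueError("singular cell matrix")
        heights = _plane_distances(cell)
        reps = [
            int(np.ceil(cutoff / heights[k])) if structure.pbc[k] else 0
            for k in range(3)
        ]
    else:
        cell = np.eye(3)
        reps = [0, 0, 0]
    shifts = np.array(
        [
            (a, b, c)
            for a in range(-reps[0], reps[0] + 1)
            for b in range(-reps[1], reps[1] + 1)
            for c in range(-reps[2], reps[2] + 1)
        ],
        dtype=int,
    )
    shift_vecs = shifts @ cell  # (S, 3)
    i_list, j_list, s_list, r_list = [], [], [], []
    for i in range(n):
        # displacement to atom j in image s: r_j + shift_s - r_i
        disp = pos[None, :, :] + shift_vecs[:, None, :] - pos[i]  # (S, N, 3)
        dist = np.linalg.norm(disp, axis=2)
        mask = (dist < cutoff) & (dist > 1e-12)
        s_sel, j_sel = np.nonzero(mask)
        order = np.lexsort((shifts[s_sel, 2], shifts[s_sel, 1], shifts[s_sel, 0], j_sel))
        j_sel, s_sel = j_sel[order], s_sel[order]
        i_list.append(np.full(len(j_sel), i))
        j_list.append(j_sel)
        s_list.append(shifts[s_sel])
        r_list.append(disp[s_sel, j_sel])
    i_idx = np.concatenate(i_list) if i_list else np.empty(0, int)
    j_idx = np.concatenate(j_list) if j_list else np.empty(0, int)
    shift = np.concatenate(s_list) if s_list else np.empty((0, 3), int)
    r_ij = np.concatenate(r_list) if r_list else np.empty((0, 3))
    d = np.linalg.norm(r_ij, axis=1) if len(r_ij) else np.empty(0)
    return NeighborTable(i_idx, j_idx, shift, r_ij, d, cutoff)
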
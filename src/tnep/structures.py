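"""In-memory containers for labeled atomic structures and tensor time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tolerance above which a rank-2 label is considered corrupted rather than
#: merely noisy: symmetrization is refused and an error raised.
ASYMMETRY_ERROR = 1e-3
#: Residual asymmetry allowed after symmetrization.
ASYMMETRY_TOL = 1e-8


class LabelAsymmetryError(ValueError):
    """A rank-2 reference tensor is too asymmetric to be a valid label."""


def symmetrize_label(a: np.ndarray, what: str = "tensor") -> np.ndarray:
    """Return (A + A^T)/2 after checking the asymmetry is below ``ASYMMETRY_ERROR``.

    Reference polarizability/susceptibility tensors are physically symmetric;
    a large antisymmetric part signals a corrupted label (e.g. mangled
    row-major ordering) and is rejected loudly.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (3, 3):
        raise ValueError(f"{what} label must be 3x3, got shape {a.shape}")
    asym = np.max(np.abs(a - a.T))
    if asym > ASYMMETRY_ERROR:
        raise LabelAsymmetryError(
            f"{what} label asymmetry {asym:.3g} exceeds {ASYMMETRY_ERROR:g}; "
            "the label looks corrupted"
        )
    return 0.5 * (a + a.T)


@dataclass
class AtomicStructure:
    """A finite or periodic atomic configuration with optional tensor labels.

    Parameters
    ----------
    species
        Chemical symbols, one per atom.
    positions
        Cartesian positions in Angstrom, shape (N, 3).
    cell
        Optional 3x3 lattice matrix in Angstrom; rows are lattice vectors.
    pbc
        Periodic flags per lattice vector.
    dipole
        Optional reference dipole moment in e*bohr, shape (3,).
    polarizability
        Optional reference molecular polarizability in bohr^3, shape (3, 3).
    susceptibility
        Optional reference (unitless) electric susceptibility, shape (3, 3).
    weight
        Nonnegative per-structure weight used in the training loss.
    """

    species: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    dipole: np.ndarray | None = None
    polarizability: np.ndarray | None = None
    susceptibility: np.ndarray | None = None
    weight: float = 1.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.species)
        if n < 1:
            raise ValueError("structure needs at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} species"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atomic positions")
        self.pbc = tuple(bool(b) for b in self.pbc)
        if len(self.pbc) != 3:
            raise ValueError("pbc must have three flags")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be a 3x3 matrix")
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("periodic structure requires a cell")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValueError("singular cell matrix")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        if self.polarizability is not None:
            self.polarizability = symmetrize_label(
                self.polarizability, "polarizability"
            )
        if self.susceptibility is not None:
            self.susceptibility = symmetrize_label(
                self.susceptibility, "susceptibility"
            )
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def label(self, kind: str) -> np.ndarray | None:
        """Return the reference tensor for a model kind (or None)."""
        if kind == "dipole":
            return self.dipole
        if kind == "polarizability":
            return self.polarizability
        if kind == "susceptibility":
            return self.susceptibility
        raise ValueError(f"unknown label kind {kind!r}")

    def with_label(self, kind: str, value: np.ndarray) -> "AtomicStructure":
        """Return a copy carrying ``value`` as the label for ``kind``."""
        kwargs = dict(
            species=list(self.species),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc,
            dipole=None if self.dipole is None else self.dipole.copy(),
            polarizability=(
                None if self.polarizability is None else self.polarizability.copy()
            ),
            susceptibility=(
                None if self.susceptibility is None else self.susceptibility.copy()
            ),
            weight=self.weight,
        )
        kwargs[kind] = np.asarray(value, dtype=float)
        return AtomicStructure(**kwargs)


@dataclass
class TensorTrajectory:
    """Uniformly sampled time series of 3-vectors (rank 1) or symmetric 3x3
    tensors (rank 2).

    ``dt`` is the sampling interval in fs.  Rank-2 frames are symmetrized on
    construction with the same corruption guard as structure labels.
    """

    dt: float
    frames: np.ndarray
    rank: int
    temperature: float | None = None
    volume: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2")
        want = (1, 3) if self.rank == 1 else (2, 3, 3)
        if self.frames.ndim != want[0] + 1 or self.frames.shape[1:] != want[1:]:
            raise ValueError(
                f"rank-{self.rank} trajectory needs frames of shape "
                f"(n, {'3' if self.rank == 1 else '3, 3'}), got "
                f"{self.frames.shape}"
            )
        if len(self.frames) < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.rank == 2:
            asym = np.max(np.abs(self.frames - np.swapaxes(self.frames, 1, 2)))
            if asym > ASYMMETRY_ERROR:
                raise LabelAsymmetryError(
                    f"rank-2 frame asymmetry {asym:.3g} exceeds "
                    f"{ASYMMETRY_ERROR:g}"
                )
            self.frames = 0.5 * (self.frames + np.swapaxes(self.frames, 1, 2))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Total span of the series in fs."""
        return (len(self.frames) - 1) * self.dt
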
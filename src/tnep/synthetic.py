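"""Synthetic datasets and trajectories with exactly known ground truth.

Three generators cover the three pillars of the package: point-charge
dipole datasets (mu = sum_i Q_i r_i, the static-charge limit that classical
force fields assume), bond-polarizability rank-2 datasets (each bond
contributes a_par along the bond and a_perp across it), and harmonic
tensor trajectories (sums of cosines at prescribed wavenumbers) that serve
as analytic oracles for the spectra pipeline.  Every generated label obeys
the same equivariance laws the models must obey, so generator bugs cannot
masquerade as model bugs.  All randomness is seeded: displacements are
drawn uniformly in a cube of the stated amplitude to bound the geometry
distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TensorModel, predict
from .structures import AtomicStructure, TensorTrajectory
from .units import FS_INV_IN_CM, angstrom_to_bohr

# simple atomic masses (u) for center-of-mass references
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
           "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45}

#: rigid water geometry (Angstrom): r_OH = 0.9572, HOH angle 104.52 deg
WATER_SPECIES = ["O", "H", "H"]
_ANG = np.deg2rad(104.52) / 2
WATER_POSITIONS = np.array([
    [0.0, 0.0, 0.0],
    [0.9572 * np.sin(_ANG), 0.0, 0.9572 * np.cos(_ANG)],
    [-0.9572 * np.sin(_ANG), 0.0, 0.9572 * np.cos(_ANG)],
])

#: TIP3P-style point charges (e)
TIP3P_CHARGES = {"O": -0.834, "H": 0.417}


@dataclass
class PointChargeSpec:
    """Settings for the point-charge dipole generator."""

    species: list[str]
    positions: np.ndarray
    charges: dict[str, float]
    amplitude: float = 0.1
    count: int = 100
    seed: int = 0
    label_noise: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        for s in set(self.species):
            if s not in self.charges:
                raise ValueError(f"no charge given for species {s!r}")


@dataclass
class BondPolarizabilitySpec:
    """Settings for the bond-polarizability generator.

    Bonds are either listed explicitly as index pairs or found per
    structure by a distance rule (``bond_cutoff``).  ``a_par`` and
    ``a_perp`` are the longitudinal and transverse bond polarizabilities in
    bohr^3; an optional ``distance_power`` p scales each bond contribution
    by (d0 / d)^p with d0 the template bond length.
    """

    species: list[str]
    positions: np.ndarray
    a_par: float = 2.0
    a_perp: float = 1.0
    bonds: list[tuple[int, int]] | None = None
    bond_cutoff: float | None = None
    distance_power: float = 0.0
    amplitude: float = 0.1
    count: int = 100
    seed: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.bonds is None and self.bond_cutoff is None:
            raise ValueError("need either an explicit bond list or a bond_cutoff")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


def displaced_structures(species, positions, amplitude, count, seed):
    """Seeded copies of a template with uniform cube displacements."""
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    out = []
    for _ in range(count):
        disp = rng.uniform(-amplitude, amplitude, size=positions.shape)
        out.append(AtomicStructure(list(species), positions + disp))
    return out


def point_charge_dipole(structure: AtomicStructure,
                        charges: dict[str, float]) -> np.ndarray:
    """mu = sum_i Q_i (r_i - r_ref) in e*bohr.

    For a neutral system the result is reference-independent; for a net
    charge the relative permanent dipole with respect to the center of
    mass is used.
    """
    q = np.array([charges[s] for s in structure.species])
    pos = structure.positions
    if abs(q.sum()) > 1e-12:
        m = np.array([_MASSES.get(s, 1.0) for s in structure.species])
        ref = (m[:, None] * pos).sum(0) / m.sum()
        pos = pos - ref
    return angstrom_to_bohr(q @ pos)


def gen_point_charge_dataset(spec: PointChargeSpec) -> list[AtomicStructure]:
    """Displaced templates labeled with their exact point-charge dipole."""
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for s in displaced_structures(
        spec.species, spec.positions, spec.amplitude, spec.count, spec.seed
    ):
        mu = point_charge_dipole(s, spec.charges)
        if spec.label_noise:
            mu = mu + spec.label_noise * rng.standard_normal(3)
        out.append(s.with_label("dipole", mu))
    return out


def bond_polarizability(structure: AtomicStructure,
                        spec: BondPolarizabilitySpec) -> np.ndarray:
    """alpha = sum_bonds [a_par rhat rhat^T + a_perp (I - rhat rhat^T)] (bohr^3)."""
    pos = structure.positions
    if spec.bonds is not None:
        bonds = spec.bonds
    else:
        n = structure.n_atoms
        bonds = [
            (i, j)
            for i in range(n) for j in range(i + 1, n)
            if np.linalg.norm(pos[j] - pos[i]) < spec.bond_cutoff
        ]
    alpha = np.zeros((3, 3))
    for i, j in bonds:
        r = pos[j] - pos[i]
        d = np.linalg.norm(r)
        rhat = r / d
        proj = np.outer(rhat, rhat)
        contrib = spec.a_par * proj + spec.a_perp * (np.eye(3) - proj)
        if spec.distance_power:
            d0 = np.linalg.norm(spec.positions[j] - spec.positions[i])
            contrib = contrib * (d0 / d) ** spec.distance_power
        alpha += contrib
    return alpha


def gen_bond_polarizability_dataset(spec: BondPolarizabilitySpec):
    """Displaced templates labeled with their bond-model polarizability."""
    out = []
    for s in displaced_structures(
        spec.species, spec.positions, spec.amplitude, spec.count, spec.seed
    ):
        out.append(s.with_label("polarizability", bond_polarizability(s, spec)))
    return out


_RANK1_CHANNELS = {"x": (0,), "y": (1,), "z": (2,)}
_RANK2_CHANNELS = {
    "xx": ((0, 0),), "yy": ((1, 1),), "zz": ((2, 2),),
    "xy": ((0, 1), (1, 0)), "xz": ((0, 2), (2, 0)), "yz": ((1, 2), (2, 1)),
    "iso": ((0, 0), (1, 1), (2, 2)),
}


def gen_harmonic_trajectory(components, dt: float, n_steps: int,
                            rank: int = 1) -> TensorTrajectory:
    """Sum-of-cosines tensor trajectory.

    ``components`` is a list of ``(channel, amplitude, wavenumber_cm1,
    phase)``.  Rank-1 channels are 'x'/'y'/'z'; rank-2 channels are
    'xx'...'yz' (symmetric fill) plus 'iso' which drives all three diagonal
    entries (a pure gamma oscillation).  Wavenumbers at or above the
    Nyquist limit of ``dt`` are rejected as aliased.
    """
    if rank not in (1, 2):
        raise ValueError("rank must be 1 or 2")
    nyquist_cm = FS_INV_IN_CM / (2.0 * dt)
    t = np.arange(n_steps) * dt
    frames = (
        np.zeros((n_steps, 3)) if rank == 1 else np.zeros((n_steps, 3, 3))
    )
    table = _RANK1_CHANNELS if rank == 1 else _RANK2_CHANNELS
    for channel, amplitude, wavenumber, phase in components:
        if channel not in table:
            raise ValueError(
                f"unknown rank-{rank} channel {channel!r}; "
                f"choose from {sorted(table)}"
            )
        if wavenumber >= nyquist_cm:
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 is at/above the Nyquist "
                f"limit {nyquist_cm:.1f} cm^-1 for dt = {dt} fs"
            )
        signal = amplitude * np.cos(
            2.0 * np.pi * (wavenumber / FS_INV_IN_CM) * t + phase
        )
        for entry in table[channel]:
            if rank == 1:
                frames[:, entry] += signal
            else:
                frames[:, entry[0], entry[1]] += signal
    return TensorTrajectory(dt=dt, frames=frames, rank=rank)


def gen_teacher_student_dataset(teacher: TensorModel, structures):
    """Label structures with a teacher model's own predictions.

    A student of identical architecture can then drive the loss RMSE term
    arbitrarily low, which makes this the strongest recovery test for the
    training pipeline.
    """
    kind = teacher.kind
    return [s.with_label(kind, predict(teacher, s)) for s in structures]
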
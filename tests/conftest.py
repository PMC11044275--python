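"""Shared fixtures: random structures, small descriptor specs, random models."""

import numpy as np
import pytest

from tnep import AtomicStructure, DescriptorSpec, TensorModel, initial_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation from a QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_cluster(rng, n_atoms=6, species=("O", "H"), box=3.0) -> AtomicStructure:
    """A finite cluster with random species and positions, min spacing 0.7 A."""
    while True:
        pos = rng.uniform(-box / 2, box / 2, (n_atoms, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        if n_atoms == 1 or np.min(d[np.triu_indices(n_atoms, 1)]) > 0.7:
            break
    syms = [species[i] for i in rng.integers(0, len(species), n_atoms)]
    return AtomicStructure(syms, pos)


def random_periodic(rng, n_atoms=4, species=("O", "H")) -> AtomicStructure:
    """A periodic structure with a mildly skewed cell, heights > 4.2 A."""
    while True:
        cell = np.diag(rng.uniform(5.0, 7.5, 3))
        cell[1, 0] = rng.uniform(-1.0, 1.0)
        cell[2, 0] = rng.uniform(-1.0, 1.0)
        cell[2, 1] = rng.uniform(-1.0, 1.0)
        vol = abs(np.linalg.det(cell))
        heights = [
            vol / np.linalg.norm(np.cross(cell[(k + 1) % 3], cell[(k + 2) % 3]))
            for k in range(3)
        ]
        if min(heights) > 4.2:
            break
    frac = rng.uniform(0, 1, (n_atoms, 3))
    pos = frac @ cell
    syms = [species[i] for i in rng.integers(0, len(species), n_atoms)]
    return AtomicStructure(syms, pos, cell=cell, pbc=(True, True, True))


@pytest.fixture
def small_spec():
    return DescriptorSpec(
        r_cut_radial=4.0, r_cut_angular=3.0,
        n_max_radial=3, n_max_angular=2, l_max=2,
        species=["O", "H"],
    )


def random_model(spec, kind="dipole", n_neurons=5, seed=0, scale=0.5) -> TensorModel:
    n_heads = 1 if kind == "dipole" else 2
    z = initial_parameters(spec, n_neurons, seed=seed, scale=scale,
                           n_heads=n_heads)
    rng = np.random.default_rng(seed + 1)
    # perturb the mixing block too so species weights are nontrivial
    if spec.n_mixing:
        z[-spec.n_mixing:] = 1.0 + 0.3 * rng.standard_normal(spec.n_mixing)
    return TensorModel(kind=kind, spec=spec, n_neurons=n_neurons, z=z)
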
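"""Tensor model: site values, partial forces, rank-1/rank-2 assembly,
equivariance, brute-force oracles, serialization."""

import numpy as np
import pytest

from tnep import (
    AtomicStructure, DescriptorContext, DescriptorSpec, TensorModel,
    initial_parameters, load_model, partial_forces, predict_rank1,
    predict_rank2, save_model, site_values, virial_form,
)
from tnep.model import ModelFormatError, as_partial_force_dict
from tnep.neighbors import NeighborTable

from conftest import random_cluster, random_periodic, random_rotation, random_model
from test_neighbors import brute_force_pairs


def brute_force_predictions(model, structure):
    """mu, alpha and the virial-form tensor from naive double loops.

    Pairs come from explicit image enumeration (no neighbor table); the
    network forward pass and the Eq-style assembly are reimplemented here
    with plain loops, independent of the package's batched paths.
    """
    spec = model.spec
    pairs = sorted(brute_force_pairs(structure, spec.r_cut_radial))
    pos = structure.positions
    cell = structure.cell if structure.cell is not None else np.eye(3)
    i_idx = np.array([p[0] for p in pairs], dtype=int)
    j_idx = np.array([p[1] for p in pairs], dtype=int)
    shift = np.array([p[2] for p in pairs], dtype=int).reshape(-1, 3)
    r_ij = pos[j_idx] + shift @ cell - pos[i_idx]
    d = np.linalg.norm(r_ij, axis=1)
    table = NeighborTable(i_idx, j_idx, shift, r_ij, d, spec.r_cut_radial)
    ctx = DescriptorContext(structure, spec, table)
    _, w = model._split()
    Q = ctx.descriptors(w)
    _, dU_dq = model.network(Q)
    dQ = ctx.pair_gradients(w)
    mu = np.zeros(3)
    W = np.zeros((3, 3))
    for p in range(len(pairs)):
        F_p = dU_dq[i_idx[p]] @ dQ[p]  # (3,)
        mu += d[p] ** 2 * F_p
        W += np.outer(r_ij[p], F_p)
    if model.rank == 2:
        U_iso = model.network(Q, head=1)[0]
        alpha = np.eye(3) * U_iso.sum() + 0.5 * (W + W.T)
    else:
        alpha = None
    return mu, alpha, W


def test_zero_weight_model_gives_bias(small_spec):
    n_net = (small_spec.length + 2) * 4 + 1
    z = np.zeros(n_net + small_spec.n_mixing)
    z[n_net - 1] = 0.7  # output bias
    z[n_net:] = 1.0
    m = TensorModel("dipole", small_spec, 4, z)
    s = AtomicStructure(["O", "H"], [[0, 0, 0], [0, 0, 1.0]])
    np.testing.assert_allclose(site_values(m, s), 0.7)


def test_isolated_atom_network_of_zero(small_spec):
    m = random_model(small_spec, seed=3)
    s = AtomicStructure(["O"], [[0, 0, 0]])
    U = site_values(m, s)
    heads, _ = m._split()
    W1, b1, w2, b2 = heads[0]
    expected = np.tanh(b1) @ w2 + b2
    np.testing.assert_allclose(U, [expected], atol=1e-14)


def test_site_values_rotation_invariant(rng, small_spec):
    m = random_model(small_spec, seed=4)
    s = random_cluster(rng, n_atoms=6)
    U0 = site_values(m, s)
    for _ in range(20):
        R = random_rotation(rng)
        U = site_values(m, AtomicStructure(s.species, s.positions @ R.T))
        np.testing.assert_allclose(U, U0, atol=1e-10)


def test_partial_forces_match_finite_differences(rng, small_spec):
    """Chain-rule partial forces vs central differences of site values."""
    m = random_model(small_spec, seed=5)
    s = random_cluster(rng, n_atoms=3)
    table, F = partial_forces(m, s)
    h = 1e-5
    scale = max(np.max(np.abs(F)), 1e-10)
    for p in range(table.n_pairs):
        i, j = int(table.i_idx[p]), int(table.j_idx[p])
        num = np.zeros(3)
        for x in range(3):
            pp = s.positions.copy(); pp[j, x] += h
            pm = s.positions.copy(); pm[j, x] -= h
            num[x] = (
                site_values(m, AtomicStructure(s.species, pp))[i]
                - site_values(m, AtomicStructure(s.species, pm))[i]
            ) / (2 * h)
        np.testing.assert_allclose(F[p], num, atol=1e-6 * scale)


def test_partial_forces_isolated_and_dict(small_spec):
    m = random_model(small_spec, seed=6)
    s = AtomicStructure(["O"], [[0, 0, 0]])
    table, F = partial_forces(m, s)
    assert len(F) == 0 and as_partial_force_dict(table, F) == {}


def test_dimer_partial_forces_axial(small_spec):
    m = random_model(small_spec, seed=7)
    s = AtomicStructure(["O", "O"], [[0, 0, 0], [0, 0, 1.4]])
    _, F = partial_forces(m, s)
    np.testing.assert_allclose(F[:, :2], 0.0, atol=1e-12)


def test_single_atom_dipole_zero(small_spec):
    m = random_model(small_spec, kind="dipole", seed=8)
    s = AtomicStructure(["O"], [[1.0, 2.0, 3.0]])
    np.testing.assert_allclose(predict_rank1(m, s), np.zeros(3))


def test_centrosymmetric_dimer_dipole_cancels(small_spec):
    m = random_model(small_spec, kind="dipole", seed=9)
    s = AtomicStructure(["O", "O"], [[0, 0, -0.7], [0, 0, 0.7]])
    np.testing.assert_allclose(predict_rank1(m, s), 0.0, atol=1e-12)


def test_rank1_equivariance(rng, small_spec):
    """||mu(Rx) - R mu(x)|| < 1e-9 over 100 random rotations."""
    m = random_model(small_spec, kind="dipole", seed=10)
    s = random_cluster(rng, n_atoms=5)
    mu = predict_rank1(m, s)
    for _ in range(100):
        R = random_rotation(rng)
        mu_r = predict_rank1(m, AtomicStructure(s.species, s.positions @ R.T))
        assert np.linalg.norm(mu_r - R @ mu) < 1e-9


def test_rank2_equivariance_and_symmetry(rng, small_spec):
    """alpha(Rx) = R alpha(x) R^T to 1e-9; output symmetric by construction."""
    m = random_model(small_spec, kind="polarizability", seed=11)
    s = random_cluster(rng, n_atoms=6)
    a = predict_rank2(m, s)
    np.testing.assert_allclose(a, a.T, atol=1e-15)
    for _ in range(100):
        R = random_rotation(rng)
        a_r = predict_rank2(m, AtomicStructure(s.species, s.positions @ R.T))
        assert np.max(np.abs(a_r - R @ a @ R.T)) < 1e-9


def test_translation_invariance_exact(rng, small_spec):
    m1 = random_model(small_spec, kind="dipole", seed=12)
    m2 = random_model(small_spec, kind="polarizability", seed=12)
    s = random_cluster(rng, n_atoms=5)
    t = rng.uniform(-20, 20, 3)
    s2 = AtomicStructure(s.species, s.positions + t)
    np.testing.assert_allclose(predict_rank1(m1, s2), predict_rank1(m1, s),
                               atol=1e-12)
    np.testing.assert_allclose(predict_rank2(m2, s2), predict_rank2(m2, s),
                               atol=1e-12)
    np.testing.assert_allclose(virial_form(m2, s2), virial_form(m2, s),
                               atol=1e-12)


def test_same_species_permutation_invariance(rng, small_spec):
    m = random_model(small_spec, kind="dipole", seed=13)
    s = random_cluster(rng, n_atoms=6, species=("H",))
    perm = rng.permutation(6)
    s2 = AtomicStructure([s.species[p] for p in perm], s.positions[perm])
    np.testing.assert_allclose(predict_rank1(m, s2), predict_rank1(m, s),
                               atol=1e-10)


def test_isolated_atom_rank2_is_U_times_identity(small_spec):
    m = random_model(small_spec, kind="polarizability", seed=14)
    s = AtomicStructure(["H"], [[0, 0, 0]])
    U = site_values(m, s, head=1)[0]  # scalar head feeds the delta-term
    np.testing.assert_allclose(predict_rank2(m, s), U * np.eye(3), atol=1e-14)


def test_brute_force_oracle(rng, small_spec):
    """predict_rank1/predict_rank2/virial_form equal naive double loops on
    random finite and periodic structures, within 1e-10."""
    for k in range(30):
        if k % 2:
            s = random_periodic(rng, n_atoms=4)
        else:
            s = random_cluster(rng, n_atoms=int(rng.integers(2, 8)))
        m1 = random_model(small_spec, kind="dipole", seed=100 + k)
        m2 = random_model(small_spec, kind="polarizability", seed=200 + k)
        mu_bf, _, _ = brute_force_predictions(m1, s)
        _, a_bf, W_bf = brute_force_predictions(m2, s)
        np.testing.assert_allclose(predict_rank1(m1, s), mu_bf, atol=1e-10)
        np.testing.assert_allclose(predict_rank2(m2, s), a_bf, atol=1e-10)
        np.testing.assert_allclose(virial_form(m2, s), W_bf, atol=1e-10)


def test_second_index_contraction_equivariant(rng, small_spec):
    """The alternative rank-1 contraction (over the partial-force index)
    also obeys the vector transformation law and translation invariance."""
    m = random_model(small_spec, kind="dipole", seed=19)
    m.contraction = "second"
    s = random_cluster(rng, n_atoms=5)
    mu = predict_rank1(m, s)
    assert np.linalg.norm(mu) > 0
    for _ in range(20):
        R = random_rotation(rng)
        mu_r = predict_rank1(m, AtomicStructure(s.species, s.positions @ R.T))
        assert np.linalg.norm(mu_r - R @ mu) < 1e-9
    s2 = AtomicStructure(s.species, s.positions + 3.0)
    np.testing.assert_allclose(predict_rank1(m, s2), mu, atol=1e-12)
    # and it genuinely differs from the first-index convention
    m.contraction = "first"
    assert np.linalg.norm(predict_rank1(m, s) - mu) > 1e-8


def test_kind_checks(small_spec):
    m = random_model(small_spec, kind="dipole", seed=15)
    s = AtomicStructure(["O", "H"], [[0, 0, 0], [0, 0, 1]])
    with pytest.raises(ValueError):
        predict_rank2(m, s)
    m2 = random_model(small_spec, kind="polarizability", seed=15)
    with pytest.raises(ValueError):
        predict_rank1(m2, s)
    m3 = random_model(small_spec, kind="susceptibility", seed=15)
    with pytest.raises(ValueError, match="periodic"):
        predict_rank2(m3, s)


def test_save_load_roundtrip(tmp_path, rng, small_spec):
    m = random_model(small_spec, kind="polarizability", seed=16)
    m.q_shift = rng.standard_normal(small_spec.length)
    m.q_scale = np.abs(rng.standard_normal(small_spec.length)) + 0.5
    path = tmp_path / "model.txt"
    save_model(m, path)
    back = load_model(path)
    assert back.kind == m.kind and back.n_neurons == m.n_neurons
    assert back.spec.species == m.spec.species
    np.testing.assert_array_equal(back.z, m.z)  # bit-identical
    np.testing.assert_array_equal(back.q_shift, m.q_shift)
    np.testing.assert_array_equal(back.q_scale, m.q_scale)
    s = random_cluster(rng, n_atoms=5)
    np.testing.assert_array_equal(predict_rank2(back, s), predict_rank2(m, s))


def test_truncated_model_file(tmp_path, small_spec):
    m = random_model(small_spec, seed=17)
    path = tmp_path / "model.txt"
    save_model(m, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:-3]) + "\n")
    with pytest.raises(ModelFormatError, match="parameters"):
        load_model(path)


def test_kind_mismatch_on_load(tmp_path, small_spec):
    m = random_model(small_spec, kind="dipole", seed=18)
    path = tmp_path / "model.txt"
    save_model(m, path)
    with pytest.raises(ModelFormatError, match="kind"):
        load_model(path, expected_kind="polarizability")


def test_parameter_count_validation(small_spec):
    with pytest.raises(ValueError, match="parameter vector"):
        TensorModel("dipole", small_spec, 4, np.zeros(3))
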
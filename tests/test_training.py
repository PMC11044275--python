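"""Losses, metrics, SNES, dataset splitting and the training loop."""

import numpy as np
import pytest

from tnep import (
    AtomicStructure, DescriptorSpec, LossConfig, PreparedDataset, SNESConfig,
    compute_metrics, loss_rank1, loss_rank2, shuffle_split, snes_minimize,
    train_model,
)
from tnep.model import predict
from tnep.synthetic import gen_teacher_student_dataset
from tnep.training import default_population, regularization

from conftest import random_cluster, random_model


@pytest.fixture
def dipole_dataset(small_spec, rng):
    teacher = random_model(small_spec, kind="dipole", seed=40)
    structures = [random_cluster(rng, n_atoms=3) for _ in range(6)]
    return teacher, gen_teacher_student_dataset(teacher, structures)


def test_exact_fit_loss_is_pure_regularization(small_spec, dipole_dataset):
    teacher, ds = dipole_dataset
    prep = PreparedDataset(ds, small_spec, "dipole", teacher.n_neurons)
    cfg0 = LossConfig(0.0, 0.0, rank=1)
    assert loss_rank1(teacher.z, prep, cfg0) == pytest.approx(0.0, abs=1e-12)
    cfg = LossConfig(1e-3, 1e-3, rank=1)
    expected_reg = regularization(teacher.z, 1e-3, 1e-3)
    assert loss_rank1(teacher.z, prep, cfg) == pytest.approx(expected_reg,
                                                             abs=1e-12)


def test_zero_parameters_zero_regularization():
    assert regularization(np.zeros(100), 1.0, 1.0) == 0.0


def test_hand_computed_rank1_loss(small_spec):
    """Single-atom structures predict mu = 0, so the loss reduces to the
    component RMSE of the labels, which we hand-compute."""
    s1 = AtomicStructure(["O"], [[0, 0, 0]], dipole=[1.0, 2.0, 2.0])
    s2 = AtomicStructure(["O"], [[0, 0, 0]], dipole=[0.0, 1.0, 0.0])
    prep = PreparedDataset([s1, s2], small_spec, "dipole", 4)
    z = np.zeros(prep.n_parameters)
    # components: 1,2,2,0,1,0 -> mean square = 10/6
    expected = np.sqrt(10.0 / 6.0)
    assert loss_rank1(z, prep, LossConfig(rank=1)) == pytest.approx(expected)


def test_hand_computed_rank2_loss(small_spec):
    """Single atoms predict alpha = b2 * I for a zero-weight network; with
    b2 = 0 the loss is the RMSE over the 6 independent components."""
    a1 = np.diag([1.0, 1.0, 1.0])
    a2 = np.array([[0, 2.0, 0], [2.0, 0, 0], [0, 0, 0.0]])
    s1 = AtomicStructure(["O"], [[0, 0, 0]], polarizability=a1)
    s2 = AtomicStructure(["O"], [[0, 0, 0]], polarizability=a2)
    prep = PreparedDataset([s1, s2], small_spec, "polarizability", 4)
    z = np.zeros(prep.n_parameters)
    # components per structure (xx, xy, xz, yy, yz, zz):
    # s1: 1,0,0,1,0,1 ; s2: 0,2,0,0,0,0 -> mean square = 7/12
    expected = np.sqrt(7.0 / 12.0)
    assert loss_rank2(z, prep, LossConfig(rank=2)) == pytest.approx(expected)


def test_structure_weights_enter_loss(small_spec):
    s1 = AtomicStructure(["O"], [[0, 0, 0]], dipole=[1.0, 0.0, 0.0], weight=3.0)
    s2 = AtomicStructure(["O"], [[0, 0, 0]], dipole=[0.0, 0.0, 0.0], weight=1.0)
    prep = PreparedDataset([s1, s2], small_spec, "dipole", 4)
    z = np.zeros(prep.n_parameters)
    # weighted mean square: (3*1 + 0) / (4 * 3) = 1/4
    assert loss_rank1(z, prep, LossConfig(rank=1)) == pytest.approx(0.5)


def test_missing_labels_rejected(small_spec, rng):
    s = random_cluster(rng, n_atoms=3)
    with pytest.raises(ValueError, match="lack"):
        PreparedDataset([s], small_spec, "dipole", 4)


def test_rank_mismatch_rejected(small_spec):
    s = AtomicStructure(["O"], [[0, 0, 0]], dipole=[1.0, 0, 0])
    prep = PreparedDataset([s], small_spec, "dipole", 4)
    with pytest.raises(ValueError):
        loss_rank2(np.zeros(prep.n_parameters), prep, LossConfig(rank=2))


# --- metrics ---------------------------------------------------------------

def test_metrics_perfect_predictions():
    ref = np.random.default_rng(0).standard_normal((20, 3))
    m = compute_metrics(ref, ref, rank=1)
    assert m.rmse == 0.0 and m.r2 == 1.0 and m.rrmse == 0.0


def test_metrics_mean_predictor():
    """Predicting the reference mean gives RRMSE = 1 and R^2 = 0 exactly."""
    ref = np.random.default_rng(1).standard_normal((50, 3))
    pred = np.full_like(ref, ref.mean())
    m = compute_metrics(pred, ref, rank=1)
    assert m.rrmse == pytest.approx(1.0)
    assert m.r2 == pytest.approx(0.0, abs=1e-12)


def test_metrics_hand_example():
    """3-sample rank-1 example with hand-computed scores."""
    ref = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    pred = np.array([[1.0, 0, 0], [0, 0.0, 0], [0, 0, 1.0]])
    m = compute_metrics(pred, ref, rank=1)
    # one error of 1 over 9 components
    assert m.rmse == pytest.approx(np.sqrt(1.0 / 9.0))
    std = np.std(ref.ravel())  # mean 1/3, variance 2/9
    assert std == pytest.approx(np.sqrt(2.0 / 9.0))
    assert m.rrmse == pytest.approx(m.rmse / std)
    ss_tot = np.sum((ref - ref.mean()) ** 2)
    assert m.r2 == pytest.approx(1.0 - 1.0 / ss_tot)


def test_metrics_rank2_splits():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((30, 3, 3))
    ref = 0.5 * (a + np.swapaxes(a, 1, 2))
    pred = ref.copy()
    pred[:, 0, 0] += 0.1  # diagonal-only error
    m = compute_metrics(pred, ref, rank=2)
    assert m.rmse_offdiag == 0.0
    assert m.rmse_diag == pytest.approx(0.1 / np.sqrt(3.0))
    assert m.rrmse_diag > 0


def test_metrics_shape_and_degenerate_errors():
    with pytest.raises(ValueError, match="shape"):
        compute_metrics(np.zeros((3, 3)), np.zeros((4, 3)), rank=1)
    with pytest.raises(ValueError, match="constant"):
        compute_metrics(np.ones((3, 3)), np.ones((3, 3)), rank=1)


def test_metrics_order_invariance():
    rng = np.random.default_rng(3)
    ref = rng.standard_normal((20, 3))
    pred = ref + 0.1 * rng.standard_normal((20, 3))
    m1 = compute_metrics(pred, ref, rank=1)
    perm = rng.permutation(20)
    m2 = compute_metrics(pred[perm], ref[perm], rank=1)
    assert m1.rmse == pytest.approx(m2.rmse)


# --- SNES ------------------------------------------------------------------

def test_snes_1d_quadratic():
    cfg = SNESConfig(generations=400, population=8, initial_sigma=1.0, seed=5)
    best, hist = snes_minimize(lambda z: float((z[0] - 3.0) ** 2), 1, cfg)
    assert abs(best[0] - 3.0) < 1e-4


def test_snes_sphere_convergence():
    """Separable convex benchmark: distance to the optimum shrinks by far
    more than 10x over the budget."""
    cfg = SNESConfig(generations=2000, population=20, initial_sigma=1.0,
                     seed=6)
    best, hist = snes_minimize(lambda z: float(z @ z), 50, cfg,
                               x0=np.ones(50))
    assert hist[-1] < 1e-6
    assert hist[-1] < hist[0] / 100.0


def test_snes_best_so_far_monotone():
    cfg = SNESConfig(generations=200, population=10, initial_sigma=0.5, seed=7)
    _, hist = snes_minimize(lambda z: float(np.sum(np.abs(z))), 10, cfg)
    assert np.all(np.diff(hist) <= 0)


def test_snes_seeded_determinism():
    cfg = SNESConfig(generations=100, population=10, initial_sigma=0.5, seed=8)
    b1, h1 = snes_minimize(lambda z: float(z @ z), 5, cfg)
    b2, h2 = snes_minimize(lambda z: float(z @ z), 5, cfg)
    np.testing.assert_array_equal(b1, b2)
    np.testing.assert_array_equal(h1, h2)


def test_snes_nan_abort():
    cfg = SNESConfig(generations=10, population=8, initial_sigma=0.5, seed=9)
    with pytest.raises(RuntimeError, match="NaN"):
        snes_minimize(lambda z: float("nan"), 3, cfg)


def test_default_population_even():
    for d in (2, 10, 100, 1000):
        assert default_population(d) % 2 == 0
        assert default_population(d) >= 4


# --- training loop ---------------------------------------------------------

def test_training_improves_loss_and_is_deterministic(small_spec, rng):
    teacher = random_model(small_spec, kind="dipole", seed=41, n_neurons=3)
    structures = [random_cluster(rng, n_atoms=3) for _ in range(30)]
    ds = gen_teacher_student_dataset(teacher, structures)
    cfg = SNESConfig(generations=120, seed=10, initial_sigma=0.2)
    m1, h1 = train_model(ds, small_spec, "dipole", LossConfig(rank=1), cfg,
                         n_neurons=3, log_every=40)
    m2, h2 = train_model(ds, small_spec, "dipole", LossConfig(rank=1), cfg,
                         n_neurons=3, log_every=40)
    np.testing.assert_array_equal(m1.z, m2.z)  # bit-identical training
    assert h1[-1]["loss"] < h1[0]["loss"]
    assert [row["loss"] for row in h1] == [row["loss"] for row in h2]


def test_training_rejects_degenerate_labels(small_spec):
    ds = [
        AtomicStructure(["O"], [[0, 0, 0]], dipole=[1.0, 1.0, 1.0])
        for _ in range(4)
    ]
    with pytest.raises(ValueError, match="identical"):
        train_model(ds, small_spec, "dipole", LossConfig(rank=1),
                    SNESConfig(generations=2), n_neurons=2)


def test_training_empty_dataset(small_spec):
    with pytest.raises(ValueError, match="empty"):
        PreparedDataset([], small_spec, "dipole", 2)


# --- shuffle-split ---------------------------------------------------------

def test_shuffle_split_permutation_case():
    splits = shuffle_split(10, 10, n_repeats=1, seed=0, holdout=0,
                           replace=False)
    train, hold = splits[0]
    assert sorted(train) == list(range(10)) and len(hold) == 0


def test_shuffle_split_determinism():
    a = shuffle_split(50, 20, n_repeats=3, seed=4, holdout=10)
    b = shuffle_split(50, 20, n_repeats=3, seed=4, holdout=10)
    for (ta, ha), (tb, hb) in zip(a, b):
        np.testing.assert_array_equal(ta, tb)
        np.testing.assert_array_equal(ha, hb)


def test_shuffle_split_protocol_shape():
    """940 structures, 140 held out, training sizes 200..800, five repeats,
    drawn with replacement from the non-holdout pool."""
    n, holdout = 940, 140
    for size in (200, 400, 600, 800):
        splits = shuffle_split(n, size, n_repeats=5, seed=1, holdout=holdout,
                               replace=True)
        assert len(splits) == 5
        ref_hold = splits[0][1]
        assert len(ref_hold) == holdout
        for train, hold in splits:
            assert len(train) == size
            np.testing.assert_array_equal(hold, ref_hold)  # fixed holdout
            assert not set(train) & set(hold)  # disjoint from holdout
        # with replacement: some repetition is overwhelmingly likely at 800
        if size == 800:
            assert len(set(splits[0][0])) < size


def test_shuffle_split_validation():
    with pytest.raises(ValueError):
        shuffle_split(10, 0)
    with pytest.raises(ValueError):
        shuffle_split(10, 10, holdout=10)
    with pytest.raises(ValueError):
        shuffle_split(10, 9, holdout=5, replace=False)
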
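"""Model training: losses, the separable natural evolution strategy (SNES),
fit metrics, and dataset splitting.

The loss is the component-wise RMSE of the predicted tensors plus L1/L2
regularization over the trainable parameters,

    L(z) = Delta(z) + lambda_1 * mean(|z|) + lambda_2 * sqrt(mean(z^2)),

where Delta runs over the 3 dipole components (rank 1) or the 6 independent
components of each symmetric tensor (rank 2, off-diagonals counted once).
SNES follows Schaul et al. (2011): per-dimension mean and step size,
symmetric (antithetic) sampling, and rank-based utility shaping; it is a
derivative-free optimizer well matched to the few-thousand-parameter
networks used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptor import DescriptorContext, DescriptorSpec, mixing_weights
from .model import TensorModel, initial_parameters
from .structures import AtomicStructure

_IU = np.triu_indices(3)  # the 6 independent components of a symmetric 3x3


@dataclass
class LossConfig:
    """Loss hyperparameters; ``per_atom_normalized`` divides predictions and
    labels by the atom count (extensive targets reported per atom/molecule)."""

    lambda_1: float = 0.0
    lambda_2: float = 0.0
    per_atom_normalized: bool = False
    rank: int = 1

    def __post_init__(self):
        if self.lambda_1 < 0 or self.lambda_2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2")


@dataclass
class SNESConfig:
    """SNES settings.  ``population`` defaults to 4 + floor(3 ln d) rounded
    up to even; learning rates default to the published schedule
    (eta_mean = 1, eta_sigma = (3 + ln d) / (5 sqrt(d)))."""

    generations: int = 1000
    population: int | None = None
    initial_sigma: float = 0.1
    seed: int = 0
    eta_mean: float = 1.0
    eta_sigma: float | None = None

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.initial_sigma <= 0:
            raise ValueError("initial_sigma must be positive")
        if self.population is not None and self.population < 4:
            raise ValueError("population must be >= 4")


@dataclass
class FitMetrics:
    """RMSE (model units), RRMSE (RMSE / std of the reference components,
    unitless) and R^2; rank-2 fits also report the diagonal/off-diagonal
    split."""

    rmse: float
    rrmse: float
    r2: float
    rmse_diag: float | None = None
    rrmse_diag: float | None = None
    rmse_offdiag: float | None = None
    rrmse_offdiag: float | None = None


def default_population(dim: int) -> int:
    pop = 4 + int(3 * np.log(dim))
    return pop + (pop % 2)


# ---------------------------------------------------------------------------
# batched dataset evaluation

class PreparedDataset:
    """Descriptor contexts for a whole dataset, stacked for fast repeated
    prediction with many candidate parameter vectors.

    All mixing-independent descriptor data are concatenated across
    structures once; ``predict_all(z)`` then needs only a handful of
    vectorized contractions regardless of the dataset size.
    """

    def __init__(self, structures: list[AtomicStructure], spec: DescriptorSpec,
                 kind: str, n_neurons: int, contraction: str = "first",
                 require_labels: bool = True,
                 q_shift: np.ndarray | None = None,
                 q_scale: np.ndarray | None = None):
        if not structures:
            raise ValueError("empty dataset")
        self.kind = kind
        self.rank = 1 if kind == "dipole" else 2
        self.spec = spec
        self.n_structures = len(structures)
        ctxs = [DescriptorContext(s, spec) for s in structures]
        self.n_atoms = np.array([s.n_atoms for s in structures])
        self.weights = np.array([s.weight for s in structures])
        atom_offset = np.concatenate([[0], np.cumsum(self.n_atoms)])
        self.atom_struct = np.repeat(np.arange(len(structures)), self.n_atoms)
        self.spec_idx = np.concatenate([c.spec_idx for c in ctxs])
        self.S_R = np.concatenate([c.S_R for c in ctxs])
        self.A = np.concatenate([c.A for c in ctxs])
        self.pair_iglob = np.concatenate(
            [c.pair_i + off for c, off in zip(ctxs, atom_offset)]
        ).astype(int)
        self.pair_struct = np.concatenate(
            [np.full(len(c.pair_i), k) for k, c in enumerate(ctxs)]
        ).astype(int)
        self.pair_sj = np.concatenate([c.pair_sj for c in ctxs]).astype(int)
        self.pair_r = np.concatenate([c.pair_r for c in ctxs])
        self.pair_d = np.concatenate([c.pair_d for c in ctxs])
        self.G_R = np.concatenate([c.G_R for c in ctxs])
        self.G_A = np.concatenate([c.G_A for c in ctxs])
        self._template = TensorModel(
            kind=kind, spec=spec, n_neurons=n_neurons,
            z=initial_parameters(spec, n_neurons,
                                 n_heads=1 if self.rank == 1 else 2),
            contraction=contraction,
        )
        self.q_shift = None if q_shift is None else np.asarray(q_shift, float)
        self.q_scale = None if q_scale is None else np.asarray(q_scale, float)
        self._fixed = None
        if not spec.trainable_pair_mixing:
            self._fixed = self._assemble(mixing_weights(spec, None))
        labels = [s.label(kind) for s in structures]
        if require_labels:
            missing = [k for k, l in enumerate(labels) if l is None]
            if missing:
                raise ValueError(
                    f"{len(missing)} structures lack a {kind} label "
                    f"(first at index {missing[0]})"
                )
            self.labels = np.array(labels)
        else:
            self.labels = None

    @property
    def n_parameters(self) -> int:
        return self._template.n_parameters

    def _assemble(self, w):
        """Descriptors Q (atoms x D) and pair gradients dQ (pairs x D x 3).

        ``w`` is the (n_mixing_channels, S, S) mixing tensor.
        """
        nR1 = self.spec.n_max_radial + 1
        wR = w[:nR1, self.spec_idx, :]
        wA = w[nR1:, self.spec_idx, :]
        qR = np.einsum("ins,nis->in", self.S_R, wR)
        qA = np.einsum("inlst,nis,nit->inl", self.A, wA, wA)
        Q = np.concatenate([qR, qA.reshape(len(qR), -1)], axis=1)
        if len(self.pair_iglob) == 0:
            return Q, np.zeros((0, self.spec.length, 3))
        si = self.spec_idx[self.pair_iglob]
        wR_pair = w[:nR1, si, self.pair_sj]
        wA_pair = w[nR1:, si, self.pair_sj]
        wA_row = w[nR1:, si, :]
        dR = wR_pair.T[:, :, None] * self.G_R
        dA = wA_pair.T[:, :, None, None] * np.einsum(
            "pnlsx,nps->pnlx", self.G_A, wA_row
        )
        dQ = np.concatenate([dR, dA.reshape(len(dR), -1, 3)], axis=1)
        return Q, dQ

    def predict_all(self, z: np.ndarray) -> np.ndarray:
        """Predictions for every structure: (S, 3) for rank 1, (S, 3, 3) for rank 2."""
        tpl = self._template
        heads, w = tpl._split(np.asarray(z, dtype=float))
        W1, b1, w2, b2 = heads[0]
        if self._fixed is not None:
            Q, dQ = self._fixed
        else:
            Q, dQ = self._assemble(w)
        if self.q_shift is not None:
            Q = Q - self.q_shift
        if self.q_scale is not None:
            Q = Q / self.q_scale
        H = np.tanh(Q @ W1.T + b1)
        dU_dq = ((1.0 - H * H) * w2) @ W1
        if self.q_scale is not None:
            dU_dq = dU_dq / self.q_scale
        F = np.einsum("pd,pdx->px", dU_dq[self.pair_iglob], dQ)
        S = self.n_structures
        if self.rank == 1:
            d2 = self.pair_d ** 2
            out = np.stack(
                [np.bincount(self.pair_struct, d2 * F[:, v], minlength=S)
                 for v in range(3)], axis=1,
            )
            return out
        W1s, b1s, w2s, b2s = heads[1]
        U = np.tanh(Q @ W1s.T + b1s) @ w2s + b2s
        Usum = np.bincount(self.atom_struct, U, minlength=S)
        W = np.empty((S, 3, 3))
        for u in range(3):
            for v in range(3):
                W[:, u, v] = np.bincount(
                    self.pair_struct, self.pair_r[:, u] * F[:, v], minlength=S
                )
        Wsym = 0.5 * (W + np.swapaxes(W, 1, 2))
        return Wsym + Usum[:, None, None] * np.eye(3)

    def _split_population(self, Z: np.ndarray):
        """Unpack a population of parameter vectors (B, n_params)."""
        spec, H = self.spec, self._template.n_neurons
        D = spec.length
        B = len(Z)
        k = 0
        heads = []
        for _ in range(self._template.n_heads):
            W1 = Z[:, k:k + H * D].reshape(B, H, D)
            k += H * D
            b1 = Z[:, k:k + H]
            k += H
            w2 = Z[:, k:k + H]
            k += H
            b2 = Z[:, k]
            k += 1
            heads.append((W1, b1, w2, b2))
        nsp = max(spec.n_species, 1)
        nch = spec.n_mixing_channels
        if spec.n_mixing:
            iu = np.triu_indices(nsp)
            npair = len(iu[0])
            packed = Z[:, k:].reshape(B, nch, npair)
            w = np.zeros((B, nch, nsp, nsp))
            w[:, :, iu[0], iu[1]] = packed
            w[:, :, iu[1], iu[0]] = packed
        else:
            w = np.ones((B, nch, nsp, nsp))
        return heads, w

    def predict_population(self, Z: np.ndarray) -> np.ndarray:
        """Predictions for a whole population of parameter vectors.

        Returns (B, S, 3) for rank 1 or (B, S, 3, 3) for rank 2.  Identical
        to stacking ``predict_all`` over rows, but one set of vectorized
        contractions for the entire population.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        heads, w = self._split_population(Z)
        W1, b1, w2, b2 = heads[0]
        B, S = len(Z), self.n_structures
        nR1 = self.S_R.shape[1]
        wR = w[:, :nR1, :, :]  # (B, nR1, nsp, nsp)
        wA = w[:, nR1:, :, :]
        wR_row = wR[:, :, self.spec_idx, :]  # (B, nR1, Ntot, nsp)
        wA_row = wA[:, :, self.spec_idx, :]
        qR = np.einsum("ins,bnis->bin", self.S_R, wR_row, optimize=True)
        qA_half = np.einsum("inlst,bnit->binls", self.A, wA_row, optimize=True)
        qA = np.einsum("binls,bnis->binl", qA_half, wA_row, optimize=True)
        Q = np.concatenate([qR, qA.reshape(B, qR.shape[1], -1)], axis=2)
        if self.q_shift is not None:
            Q = Q - self.q_shift
        if self.q_scale is not None:
            Q = Q / self.q_scale
        Hact = np.tanh(np.matmul(Q, np.swapaxes(W1, 1, 2)) + b1[:, None, :])
        dU_dq = np.matmul((1.0 - Hact * Hact) * w2[:, None, :], W1)
        if self.q_scale is not None:
            dU_dq = dU_dq / self.q_scale
        si = self.spec_idx[self.pair_iglob]
        wR_pair = wR[:, :, si, self.pair_sj]  # (B, nR1, P)
        wA_pair = wA[:, :, si, self.pair_sj]  # (B, nA1, P)
        wA_rowp = wA[:, :, si, :]  # (B, nA1, P, nsp)
        dU_pairs = dU_dq[:, self.pair_iglob]  # (B, P, D)
        # radial part of F: per-channel mixing weight times basis gradient
        dU_R = dU_pairs[:, :, :nR1] * np.swapaxes(wR_pair, 1, 2)
        F = np.einsum("bpn,pnx->bpx", dU_R, self.G_R, optimize=True)
        if self.G_A.size:
            L = self.A.shape[2]
            nA1 = self.A.shape[1]
            dU_A = dU_pairs[:, :, nR1:].reshape(B, -1, nA1, L)
            dU_Aw = dU_A * np.swapaxes(wA_pair, 1, 2)[:, :, :, None]
            T = np.einsum("pnlsx,bnps->bpnlx", self.G_A, wA_rowp,
                          optimize=True)
            F = F + np.einsum("bpnlx,bpnl->bpx", T, dU_Aw, optimize=True)

        def _scatter(index, length, weights):
            idx = (np.arange(B)[:, None] * length + index[None, :]).ravel()
            return np.bincount(
                idx, weights.ravel(), minlength=B * length
            ).reshape(B, length)

        if self.rank == 1:
            d2 = self.pair_d ** 2
            return np.stack(
                [_scatter(self.pair_struct, S, d2 * F[:, :, v])
                 for v in range(3)], axis=2,
            )
        W1s, b1s, w2s, b2s = heads[1]
        Hs = np.tanh(np.matmul(Q, np.swapaxes(W1s, 1, 2)) + b1s[:, None, :])
        U = np.einsum("bnh,bh->bn", Hs, w2s) + b2s[:, None]
        Usum = _scatter(self.atom_struct, S, U)
        W = np.empty((B, S, 3, 3))
        for u in range(3):
            for v in range(3):
                W[:, :, u, v] = _scatter(
                    self.pair_struct, S, self.pair_r[:, u] * F[:, :, v]
                )
        Wsym = 0.5 * (W + np.swapaxes(W, 2, 3))
        return Wsym + Usum[:, :, None, None] * np.eye(3)

    def loss_population(self, Z: np.ndarray, config: "LossConfig") -> np.ndarray:
        """Vectorized loss for a population; matches loss_rank1/loss_rank2."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        pred = self.predict_population(Z)
        ref = np.broadcast_to(self.labels, pred.shape)
        if config.per_atom_normalized:
            n = self.n_atoms.reshape((1, -1) + (1,) * (pred.ndim - 2))
            pred, ref = pred / n, ref / n
        if self.rank == 1:
            p = pred
            r = ref
        else:
            p = pred[:, :, _IU[0], _IU[1]]
            r = ref[:, :, _IU[0], _IU[1]]
        w = self.weights[None, :, None]
        rmse = np.sqrt(
            np.sum(w * (p - r) ** 2, axis=(1, 2))
            / (np.sum(self.weights) * p.shape[2])
        )
        reg = np.zeros(len(Z))
        if config.lambda_1:
            reg += config.lambda_1 * np.mean(np.abs(Z), axis=1)
        if config.lambda_2:
            reg += config.lambda_2 * np.sqrt(np.mean(Z * Z, axis=1))
        return rmse + reg


# ---------------------------------------------------------------------------
# losses and metrics

def regularization(z: np.ndarray, lambda_1: float, lambda_2: float) -> float:
    """lambda_1 * mean(|z|) + lambda_2 * sqrt(mean(z^2)), means over parameters."""
    z = np.asarray(z, dtype=float)
    out = 0.0
    if lambda_1:
        out += lambda_1 * np.mean(np.abs(z))
    if lambda_2:
        out += lambda_2 * np.sqrt(np.mean(z * z))
    return out


def _component_matrix(values: np.ndarray, rank: int) -> np.ndarray:
    """Independent components per structure: (S, 3) or (S, 6)."""
    values = np.asarray(values, dtype=float)
    if rank == 1:
        return values.reshape(len(values), 3)
    return values[:, _IU[0], _IU[1]]


def _weighted_rmse(pred, ref, weights) -> float:
    """RMSE over components with per-structure weights."""
    diff2 = (pred - ref) ** 2
    w = np.repeat(weights[:, None], diff2.shape[1], axis=1)
    return float(np.sqrt(np.sum(w * diff2) / np.sum(w)))


def _rmse_term(prepared: PreparedDataset, z, config: LossConfig) -> float:
    pred = prepared.predict_all(z)
    ref = prepared.labels
    if config.per_atom_normalized:
        n = prepared.n_atoms.reshape((-1,) + (1,) * (pred.ndim - 1))
        pred, ref = pred / n, ref / n
    return _weighted_rmse(
        _component_matrix(pred, prepared.rank),
        _component_matrix(ref, prepared.rank),
        prepared.weights,
    )


def loss_rank1(z, prepared: PreparedDataset, config: LossConfig) -> float:
    """Dipole loss: component RMSE over the dataset plus regularization."""
    if prepared.rank != 1:
        raise ValueError("loss_rank1 needs a rank-1 (dipole) dataset")
    return _rmse_term(prepared, z, config) + regularization(
        z, config.lambda_1, config.lambda_2
    )


def loss_rank2(z, prepared: PreparedDataset, config: LossConfig) -> float:
    """Polarizability/susceptibility loss over the 6 independent components."""
    if prepared.rank != 2:
        raise ValueError("loss_rank2 needs a rank-2 dataset")
    return _rmse_term(prepared, z, config) + regularization(
        z, config.lambda_1, config.lambda_2
    )


def compute_metrics(predictions, references, rank: int,
                    n_atoms=None) -> FitMetrics:
    """RMSE / RRMSE / R^2 over flattened independent components.

    ``n_atoms`` (optional, per structure) normalizes both sides per atom.
    RRMSE is the RMSE divided by the standard deviation of the reference
    components; R^2 = 1 - SS_res / SS_tot, so a constant predictor at the
    reference mean scores exactly 0.
    """
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.shape != references.shape:
        raise ValueError(
            f"shape mismatch: {predictions.shape} vs {references.shape}"
        )
    if n_atoms is not None:
        n = np.asarray(n_atoms).reshape((-1,) + (1,) * (predictions.ndim - 1))
        predictions, references = predictions / n, references / n
    p = _component_matrix(predictions, rank)
    r = _component_matrix(references, rank)

    def _scores(pc, rc):
        std = float(np.std(rc))
        if std == 0:
            raise ValueError("reference components are constant; RRMSE undefined")
        rmse = float(np.sqrt(np.mean((pc - rc) ** 2)))
        ss_res = float(np.sum((pc - rc) ** 2))
        ss_tot = float(np.sum((rc - np.mean(rc)) ** 2))
        return rmse, rmse / std, 1.0 - ss_res / ss_tot

    rmse, rrmse, r2 = _scores(p.ravel(), r.ravel())
    if rank == 1:
        return FitMetrics(rmse=rmse, rrmse=rrmse, r2=r2)
    diag = np.diagonal(predictions, axis1=1, axis2=2)
    rdiag = np.diagonal(references, axis1=1, axis2=2)
    off_idx = ([0, 0, 1], [1, 2, 2])
    poff = predictions[:, off_idx[0], off_idx[1]]
    roff = references[:, off_idx[0], off_idx[1]]
    rmse_d, rrmse_d, _ = _scores(diag.ravel(), rdiag.ravel())
    rmse_o, rrmse_o, _ = _scores(poff.ravel(), roff.ravel())
    return FitMetrics(
        rmse=rmse, rrmse=rrmse, r2=r2,
        rmse_diag=rmse_d, rrmse_diag=rrmse_d,
        rmse_offdiag=rmse_o, rrmse_offdiag=rrmse_o,
    )


# ---------------------------------------------------------------------------
# SNES

def snes_minimize(objective, dim: int, config: SNESConfig,
                  x0: np.ndarray | None = None,
                  sigma0: np.ndarray | None = None,
                  callback=None, batch_objective=None):
    """Separable natural evolution strategy minimization.

    Samples symmetric (antithetic) Gaussian populations, updates a
    per-dimension mean and step size with rank-based utilities, and returns
    the best parameter vector ever evaluated together with the per-
    generation best-so-far objective history (non-increasing).  Identical
    seeds give bit-identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    pop = config.population or default_population(dim)
    pop += pop % 2
    eta_mu = config.eta_mean
    eta_sigma = (
        config.eta_sigma
        if config.eta_sigma is not None
        else (3.0 + np.log(dim)) / (5.0 * np.sqrt(dim))
    )
    mu = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float).copy()
    sigma = (
        np.full(dim, config.initial_sigma)
        if sigma0 is None
        else np.asarray(sigma0, dtype=float).copy()
    )
    # rank-based utility shaping (Schaul et al.)
    ranks = np.arange(1, pop + 1)
    raw = np.maximum(0.0, np.log(pop / 2.0 + 1.0) - np.log(ranks))
    utilities = raw / raw.sum() - 1.0 / pop

    best_z, best_f = None, np.inf
    history = np.empty(config.generations)
    for gen in range(config.generations):
        half = rng.standard_normal((pop // 2, dim))
        S = np.concatenate([half, -half])
        Z = mu + sigma * S
        if batch_objective is not None:
            f = np.asarray(batch_objective(Z), dtype=float)
        else:
            f = np.array([objective(z) for z in Z])
        if np.any(np.isnan(f)):
            raise RuntimeError(
                f"NaN objective in generation {gen}; aborting SNES"
            )
        order = np.argsort(f, kind="stable")
        k = order[0]
        if f[k] < best_f:
            best_f = float(f[k])
            best_z = Z[k].copy()
        Su = S[order]
        grad_mu = utilities @ Su
        grad_sigma = utilities @ (Su * Su - 1.0)
        mu = mu + eta_mu * sigma * grad_mu
        sigma = sigma * np.exp(0.5 * eta_sigma * grad_sigma)
        history[gen] = best_f
        if callback is not None:
            callback(gen, best_z, best_f)
    return best_z, history


# ---------------------------------------------------------------------------
# high-level training

def train_model(dataset: list[AtomicStructure], spec: DescriptorSpec,
                kind: str, loss_config: LossConfig, snes_config: SNESConfig,
                n_neurons: int = 20, validation=None, log_every: int = 50,
                contraction: str = "first", standardize: bool = False):
    """Fit a tensorial model to a labeled dataset with SNES.

    With ``standardize`` (default) the descriptor channels are shifted and
    scaled to zero mean / unit variance over the training set (at unit
    mixing weights); the transform is stored in the returned model.  SNES
    explores all parameters with a common step size, so channels of very
    different magnitude otherwise slow it down badly.

    Returns ``(model, history)`` where ``history`` is a list of dicts with
    the generation index, loss, and train (plus optional validation)
    metrics, logged every ``log_every`` generations and at the end.
    """
    if kind == "dipole" and loss_config.rank != 1:
        raise ValueError("dipole models use a rank-1 loss")
    if kind != "dipole" and loss_config.rank != 2:
        raise ValueError(f"{kind} models use a rank-2 loss")
    prepared = PreparedDataset(dataset, spec, kind, n_neurons, contraction)
    # fail early on degenerate labels
    ref = _component_matrix(prepared.labels, prepared.rank)
    if np.std(ref) == 0:
        raise ValueError("all labels identical; RRMSE undefined")
    q_shift = q_scale = None
    if standardize:
        Q0 = prepared._assemble(mixing_weights(spec, None))[0]
        q_shift = Q0.mean(axis=0)
        std = Q0.std(axis=0)
        q_scale = np.where(std > 1e-10, std, 1.0)
        prepared.q_shift, prepared.q_scale = q_shift, q_scale
    prepared_val = (
        PreparedDataset(validation, spec, kind, n_neurons, contraction,
                        q_shift=q_shift, q_scale=q_scale)
        if validation else None
    )
    loss_fn = loss_rank1 if prepared.rank == 1 else loss_rank2

    def objective(z):
        return loss_fn(z, prepared, loss_config)

    history: list[dict] = []

    def log(gen, z, f):
        if gen % log_every and gen != snes_config.generations - 1:
            return
        row = {"generation": gen, "loss": f}
        m = compute_metrics(
            prepared.predict_all(z), prepared.labels, prepared.rank,
            prepared.n_atoms if loss_config.per_atom_normalized else None,
        )
        row.update({"rmse": m.rmse, "rrmse": m.rrmse, "r2": m.r2})
        if prepared.rank == 2:
            row.update({
                "rmse_diag": m.rmse_diag, "rrmse_diag": m.rrmse_diag,
                "rmse_offdiag": m.rmse_offdiag,
                "rrmse_offdiag": m.rrmse_offdiag,
            })
        if prepared_val is not None:
            mv = compute_metrics(
                prepared_val.predict_all(z), prepared_val.labels,
                prepared.rank,
                prepared_val.n_atoms if loss_config.per_atom_normalized else None,
            )
            row.update({"val_rmse": mv.rmse, "val_rrmse": mv.rrmse,
                        "val_r2": mv.r2})
        history.append(row)

    x0 = initial_parameters(spec, n_neurons,
                            n_heads=1 if prepared.rank == 1 else 2)
    best_z, _ = snes_minimize(
        objective, prepared.n_parameters, snes_config, x0=x0, callback=log,
        batch_objective=lambda Z: prepared.loss_population(Z, loss_config),
    )
    model = TensorModel(
        kind=kind, spec=spec, n_neurons=n_neurons, z=best_z,
        per_atom_normalized=loss_config.per_atom_normalized,
        contraction=contraction, q_shift=q_shift, q_scale=q_scale,
    )
    return model, history


# ---------------------------------------------------------------------------
# dataset splitting

def shuffle_split(n_total: int, train_size: int, n_repeats: int = 1,
                  seed: int = 0, holdout: int = 0, replace: bool = True):
    """Shuffle-split protocol: a fixed holdout set plus ``n_repeats``
    training sets drawn from the remaining pool.

    With ``replace=True`` training sets are random selections with
    replacement (so a structure may recur); with ``replace=False`` they are
    subsets.  Returns a list of ``(train_indices, holdout_indices)`` pairs;
    the holdout is identical across repeats and disjoint from the pool.
    """
    if train_size <= 0:
        raise ValueError("train_size must be positive")
    if holdout < 0 or holdout >= n_total:
        raise ValueError("holdout must be in [0, n_total)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    holdout_idx = np.sort(perm[:holdout])
    pool = perm[holdout:]
    if not replace and train_size > len(pool):
        raise ValueError("train_size exceeds the pool without replacement")
    splits = []
    for _ in range(n_repeats):
        if replace:
            train = rng.choice(pool, size=train_size, replace=True)
        else:
            train = rng.permutation(pool)[:train_size]
        splits.append((train, holdout_idx.copy()))
    return splits
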
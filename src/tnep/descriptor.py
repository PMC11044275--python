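"""Atom-centered invariant descriptors and their pair gradients.

Each atom i is represented by a vector q_i of rotation-, translation- and
same-species-permutation-invariant components built from its neighborhood:

* radial channels   q^R_{i,n} = sum_j w(s_i, s_j) g_n(d_ij),
* angular channels  q^A_{i,n,l} = sum_{j != k} w(s_i,s_j) w(s_i,s_k)
                                  g_n(d_ij) g_n(d_ik) P_l(cos theta_jik),

with g_n a Chebyshev radial basis T_n(2 d / r_cut - 1) damped by the smooth
cutoff function and P_l the Legendre polynomials (l = 1..l_max).  The
species-pair mixing weights w(s, s') default to 1 and can be appended to
the trainable parameter vector.

The per-structure :class:`DescriptorContext` caches everything that does
not depend on the mixing weights, so that descriptors and their gradients
with respect to the neighbor displacements r_ij can be reassembled cheaply
for many candidate parameter vectors during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbors import NeighborTable, build_neighbor_table
from .structures import AtomicStructure


@dataclass
class DescriptorSpec:
    """Hyperparameters of the invariant descriptor.

    ``r_cut_angular`` must not exceed ``r_cut_radial``; the descriptor
    length is (n_max_radial + 1) + (n_max_angular + 1) * l_max.
    """

    r_cut_radial: float
    r_cut_angular: float
    n_max_radial: int
    n_max_angular: int
    l_max: int
    species: list[str] = field(default_factory=list)
    trainable_pair_mixing: bool = True

    def __post_init__(self):
        if self.r_cut_radial <= 0 or self.r_cut_angular <= 0:
            raise ValueError("cutoffs must be positive")
        if self.r_cut_angular > self.r_cut_radial + 1e-12:
            raise ValueError("angular cutoff must not exceed radial cutoff")
        if min(self.n_max_radial, self.n_max_angular, self.l_max) < 0:
            raise ValueError("basis sizes must be nonnegative")
        self.species = list(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def length(self) -> int:
        return (self.n_max_radial + 1) + (self.n_max_angular + 1) * self.l_max

    @property
    def n_mixing_channels(self) -> int:
        """Channels carrying their own species-pair weights: one per radial
        basis index and one per angular basis index (shared across l)."""
        return (self.n_max_radial + 1) + (self.n_max_angular + 1)

    @property
    def n_mixing(self) -> int:
        """Trainable species-pair mixing weights: a symmetric
        (n_species x n_species) block per mixing channel, mirroring the
        species-resolved expansion coefficients of NEP descriptors."""
        if not self.trainable_pair_mixing:
            return 0
        s = self.n_species
        return self.n_mixing_channels * (s * (s + 1) // 2)

    def species_index(self, symbols) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.species)}
        try:
            return np.array([lookup[s] for s in symbols], dtype=int)
        except KeyError as exc:
            raise ValueError(f"species {exc.args[0]!r} not in model species "
                             f"{self.species}")


def mixing_weights(spec: DescriptorSpec, packed: np.ndarray | None) -> np.ndarray:
    """Expand packed mixing weights to a (n_mixing_channels, S, S) tensor of
    symmetric species-pair matrices.

    ``packed`` may be None/empty (all-ones: mixing disabled), a flat vector
    of n_mixing_channels * S(S+1)/2 upper-triangular entries, or a single
    (S, S) matrix which is broadcast over channels.
    """
    s = max(spec.n_species, 1)
    nch = spec.n_mixing_channels
    if packed is None or np.size(packed) == 0:
        return np.ones((nch, s, s))
    packed = np.asarray(packed, dtype=float)
    if packed.ndim == 2:
        if packed.shape != (s, s):
            raise ValueError(f"mixing matrix must be {s}x{s}")
        return np.broadcast_to(packed, (nch, s, s)).copy()
    iu = np.triu_indices(s)
    npair = len(iu[0])
    if packed.size != nch * npair:
        raise ValueError(
            f"expected {nch * npair} mixing weights, got {packed.size}"
        )
    packed = packed.reshape(nch, npair)
    w = np.zeros((nch, s, s))
    w[:, iu[0], iu[1]] = packed
    w[:, iu[1], iu[0]] = packed
    return w


def cutoff_function(d, r_cut: float):
    """Smooth cutoff f_c(d) = (1 + cos(pi d / r_cut)) / 2 for d < r_cut, else 0.

    C^1 at the cutoff: both f_c and f_c' vanish at d = r_cut.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    d = np.asarray(d, dtype=float)
    out = np.where(d < r_cut, 0.5 * (1.0 + np.cos(np.pi * d / r_cut)), 0.0)
    return out if out.ndim else float(out)


def cutoff_derivative(d, r_cut: float):
    """d f_c / d d; zero at and beyond the cutoff."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    d = np.asarray(d, dtype=float)
    out = np.where(
        d < r_cut, -0.5 * np.pi / r_cut * np.sin(np.pi * d / r_cut), 0.0
    )
    return out if out.ndim else float(out)


def radial_basis(d: np.ndarray, r_cut: float, n_max: int):
    """Values and d-derivatives of g_n(d) = T_n(2 d / r_cut - 1) f_c(d).

    Returns arrays of shape (n_max + 1, len(d)).  Chebyshev recurrence for
    T_n; T_n' = n U_{n-1} via the second-kind recurrence.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    m = len(d)
    x = 2.0 * d / r_cut - 1.0
    T = np.empty((n_max + 1, m))
    dT = np.empty((n_max + 1, m))
    T[0] = 1.0
    dT[0] = 0.0
    if n_max >= 1:
        T[1] = x
        dT[1] = 1.0
        U_prev, U = np.ones(m), 2.0 * x  # U_0, U_1
        for n in range(2, n_max + 1):
            T[n] = 2.0 * x * T[n - 1] - T[n - 2]
            dT[n] = n * U
            U_prev, U = U, 2.0 * x * U - U_prev
    fc = cutoff_function(d, r_cut)
    dfc = cutoff_derivative(d, r_cut)
    inside = d < r_cut
    g = np.where(inside, T * fc, 0.0)
    gp = np.where(inside, dT * (2.0 / r_cut) * fc + T * dfc, 0.0)
    return g, gp


def legendre_basis(c: np.ndarray, l_max: int):
    """P_l and P_l' for l = 1..l_max on cosines c (any shape).

    Returns arrays of shape (l_max, *c.shape).  Bonnet recurrence for
    values; P_l'(x) = l P_{l-1}(x) + x P_{l-1}'(x) for derivatives.
    """
    c = np.asarray(c, dtype=float)
    P = np.empty((l_max + 1,) + c.shape)
    dP = np.empty_like(P)
    P[0] = 1.0
    dP[0] = 0.0
    if l_max >= 1:
        P[1] = c
        dP[1] = 1.0
        for l in range(2, l_max + 1):
            P[l] = ((2 * l - 1) * c * P[l - 1] - (l - 1) * P[l - 2]) / l
            dP[l] = l * P[l - 1] + c * dP[l - 1]
    return P[1:], dP[1:]


class DescriptorContext:
    """Mixing-independent descriptor data for one structure.

    Stores species-resolved radial sums, angular double sums, and the
    corresponding per-pair gradient blocks, so that for any symmetric
    mixing matrix ``w`` the descriptors Q (N x D) and pair gradients
    dQ (P x D x 3) follow from a few contractions.
    """

    def __init__(self, structure: AtomicStructure, spec: DescriptorSpec,
                 table: NeighborTable | None = None):
        if not spec.species:
            spec.species = sorted(set(structure.species))
        self.spec = spec
        self.structure = structure
        if table is None:
            table = build_neighbor_table(structure, spec.r_cut_radial)
        elif table.cutoff < spec.r_cut_radial - 1e-12:
            raise ValueError("neighbor table cutoff smaller than descriptor cutoff")
        self.table = table
        self._precompute()

    def _precompute(self):
        spec, table = self.spec, self.table
        n = self.structure.n_atoms
        nsp = spec.n_species
        nR, nA, L = spec.n_max_radial, spec.n_max_angular, spec.l_max
        self.spec_idx = spec.species_index(self.structure.species)
        P = table.n_pairs
        self.pair_i = table.i_idx
        self.pair_j = table.j_idx
        self.pair_r = table.r_ij
        self.pair_d = table.d
        self.pair_sj = (
            self.spec_idx[table.j_idx] if P else np.empty(0, int)
        )

        # -- radial block ------------------------------------------------
        self.S_R = np.zeros((n, nR + 1, nsp))
        self.G_R = np.zeros((P, nR + 1, 3))
        if P:
            g, gp = radial_basis(self.pair_d, spec.r_cut_radial, nR)
            rhat = self.pair_r / self.pair_d[:, None]
            np.add.at(
                self.S_R,
                (self.pair_i, slice(None), self.pair_sj),
                g.T,
            )
            self.G_R = gp.T[:, :, None] * rhat[:, None, :]

        # -- angular block ----------------------------------------------
        self.A = np.zeros((n, nA + 1, L, nsp, nsp))
        self.G_A = np.zeros((P, nA + 1, L, nsp, 3))
        if P == 0 or L == 0:
            return
        ang_mask = self.pair_d < spec.r_cut_angular
        for i in range(n):
            sel = np.nonzero((self.pair_i == i) & ang_mask)[0]
            m = len(sel)
            if m == 0:
                continue
            rk = self.pair_r[sel]
            dk = self.pair_d[sel]
            sk = self.pair_sj[sel]
            g, gp = radial_basis(dk, spec.r_cut_angular, nA)  # (nA+1, m)
            rhat = rk / dk[:, None]
            C = np.clip(rhat @ rhat.T, -1.0, 1.0)  # (m, m)
            Pl, dPl = legendre_basis(C, L)  # (L, m, m)
            onehot = np.zeros((m, nsp))
            onehot[np.arange(m), sk] = 1.0
            # A[i, n, l, s, s'] = sum_{j != k} g_nj g_nk P_ljk
            M = g[:, None, :, None] * g[:, None, None, :] * Pl[None, :, :, :]
            idx = np.arange(m)
            M[:, :, idx, idx] = 0.0
            self.A[i] = np.einsum("nljk,js,kt->nlst", M, onehot, onehot)
            # gradient wrt moving neighbor a (pair sel[a]):
            # 2 sum_{k != a} [ gp_na rhat_a g_nk P_lak
            #                + g_na g_nk dP_lak (rhat_k/d_a - C_ak rhat_a/d_a) ]
            # dC_ak/dr_ia = rk_k/(d_a d_k) - C_ak r_a/d_a^2
            #             = (rhat_k - C_ak rhat_a)/d_a
            offdiag = 1.0 - np.eye(m)
            dC = (rhat[None, :, :] - C[:, :, None] * rhat[:, None, :]) \
                / dk[:, None, None]  # (a, k, 3)
            term1 = np.einsum(
                "na,ax,nk,lak,ak,ks->nalsx",
                gp, rhat, g, Pl, offdiag, onehot,
            )
            term2 = np.einsum(
                "na,nk,lak,akx,ak,ks->nalsx",
                g, g, dPl, dC, offdiag, onehot,
            )
            self.G_A[sel] = 2.0 * np.transpose(term1 + term2, (1, 0, 2, 3, 4))

    # -- assembly with mixing weights ------------------------------------

    def descriptors(self, w: np.ndarray | None = None) -> np.ndarray:
        """Descriptor matrix Q of shape (N, length) for mixing weights ``w``
        ((n_mixing_channels, S, S) tensor; None means all ones)."""
        spec = self.spec
        w = mixing_weights(spec, None) if w is None else w
        nR1 = spec.n_max_radial + 1
        wR = w[:nR1, self.spec_idx, :]  # (nR1, N, nsp)
        wA = w[nR1:, self.spec_idx, :]  # (nA1, N, nsp)
        qR = np.einsum("ins,nis->in", self.S_R, wR)
        qA = np.einsum("inlst,nis,nit->inl", self.A, wA, wA)
        return np.concatenate([qR, qA.reshape(len(qR), -1)], axis=1)

    def pair_gradients(self, w: np.ndarray | None = None) -> np.ndarray:
        """Gradients dq_i/dr_ij of shape (P, length, 3), aligned with pairs."""
        spec = self.spec
        w = mixing_weights(spec, None) if w is None else w
        P = len(self.pair_i)
        if P == 0:
            return np.zeros((0, spec.length, 3))
        nR1 = spec.n_max_radial + 1
        si = self.spec_idx[self.pair_i]
        wR_pair = w[:nR1, si, self.pair_sj]  # (nR1, P)
        wA_pair = w[nR1:, si, self.pair_sj]  # (nA1, P)
        wA_row = w[nR1:, si, :]  # (nA1, P, nsp)
        dR = wR_pair.T[:, :, None] * self.G_R
        dA = wA_pair.T[:, :, None, None] * np.einsum(
            "pnlsx,nps->pnlx", self.G_A, wA_row
        )
        return np.concatenate([dR, dA.reshape(P, -1, 3)], axis=1)


def compute_descriptor(structure: AtomicStructure, table: NeighborTable | None,
                       spec: DescriptorSpec,
                       mixing: np.ndarray | None = None) -> np.ndarray:
    """Per-atom descriptor vectors q_i (N x length).

    ``mixing`` is a symmetric species-pair matrix or packed upper triangle;
    None means w = 1 everywhere.
    """
    ctx = DescriptorContext(structure, spec, table)
    w = _as_matrix(spec, mixing)
    return ctx.descriptors(w)


def descriptor_pair_gradients(structure: AtomicStructure,
                              table: NeighborTable | None,
                              spec: DescriptorSpec,
                              mixing: np.ndarray | None = None):
    """Pair gradients dq_i/dr_ij.

    Returns ``(pairs, grads)`` where ``pairs`` is the neighbor table used
    and ``grads`` has shape (n_pairs, length, 3) aligned with its pairs.
    """
    ctx = DescriptorContext(structure, spec, table)
    w = _as_matrix(spec, mixing)
    return ctx.table, ctx.pair_gradients(w)


def _as_matrix(spec: DescriptorSpec, mixing) -> np.ndarray | None:
    if mixing is None:
        return None
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim in (1, 2):
        return mixing_weights(spec, mixing)
    return mixing
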
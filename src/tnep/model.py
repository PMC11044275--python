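"""Tensorial NEP models: network site values, partial forces, and the
rank-1 / rank-2 tensor assembly.

A single-hidden-layer perceptron with tanh activation maps each atom's
invariant descriptor q_i to a scalar site value U_i, whose physical
dimension depends on the model kind (charge for dipole models,
polarizability for rank-2 models).  Predictions are built from the partial
forces dU_i/dr_ij:

* virial form    W^{uv}   = sum_i sum_j r_ij^u dU_i/dr_ij^v
* rank 1 (mu)    mu^v     = sum_i sum_j d_ij^2 dU_i/dr_ij^v
  (the virial-form tensor contracted with r_ij over its first index,
  giving the squared distance; convention recorded in the model file)
* rank 2 (alpha) a^{uv}   = delta^{uv} sum_i U_i + (W + W^T)^{uv} / 2

All three are exactly translation invariant (functions of r_ij only),
rotationally equivariant, and invariant under same-species permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptor import DescriptorContext, DescriptorSpec, mixing_weights
from .structures import AtomicStructure

KINDS = ("dipole", "polarizability", "susceptibility")
UNITS = {"dipole": "e*bohr", "polarizability": "bohr^3", "susceptibility": "unitless"}

MODEL_FORMAT = "tnep-model"
MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """Model file is malformed or inconsistent with the requested use."""


@dataclass
class TensorModel:
    """A trained (or initialized) tensorial model.

    ``z`` is the flat trainable parameter vector: hidden weights (row per
    neuron), hidden biases, output weights, output bias, then — for rank-2
    models — a second network block of the same shape, and finally the
    packed species-pair mixing weights when the descriptor declares them
    trainable.

    Rank-2 models carry two independent site quantities: the *pair* head,
    whose gradients build the virial-form term, and the *scalar* head,
    whose per-atom values feed the isotropic delta-term.  Tying both roles
    to one network couples its values to its gradients and measurably
    limits the attainable fit; the two-head form mirrors the doubled
    network-parameter count of reference TNEP polarizability models.
    """

    kind: str
    spec: DescriptorSpec
    n_neurons: int
    z: np.ndarray
    per_atom_normalized: bool = False
    contraction: str = "first"
    #: optional per-channel descriptor standardization (computed from the
    #: training set): the network sees (q - q_shift) / q_scale
    q_shift: np.ndarray | None = None
    q_scale: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.contraction not in ("first", "second"):
            raise ValueError("contraction must be 'first' or 'second'")
        self.z = np.asarray(self.z, dtype=float).ravel()
        if len(self.z) != self.n_parameters:
            raise ValueError(
                f"parameter vector has {len(self.z)} entries, expected "
                f"{self.n_parameters}"
            )
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite model parameters")
        for name in ("q_shift", "q_scale"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).reshape(self.spec.length)
                setattr(self, name, v)
        if self.q_scale is not None and np.any(self.q_scale <= 0):
            raise ValueError("q_scale entries must be positive")

    @property
    def unit(self) -> str:
        return UNITS[self.kind]

    @property
    def rank(self) -> int:
        return 1 if self.kind == "dipole" else 2

    @property
    def n_network_parameters(self) -> int:
        """Parameters of one network head."""
        return (self.spec.length + 2) * self.n_neurons + 1

    @property
    def n_heads(self) -> int:
        return 1 if self.rank == 1 else 2

    @property
    def n_parameters(self) -> int:
        return self.n_heads * self.n_network_parameters + self.spec.n_mixing

    def _split(self, z: np.ndarray | None = None):
        """Unpack z into (heads, mixing) where ``heads`` is a list of
        (W1, b1, w2, b2) tuples — [pair] for rank 1, [pair, scalar] for
        rank 2."""
        if z is None:
            z = self.z
        D, H = self.spec.length, self.n_neurons
        heads = []
        k = 0
        for _ in range(self.n_heads):
            W1 = z[k:k + H * D].reshape(H, D)
            k += H * D
            b1 = z[k:k + H]
            k += H
            w2 = z[k:k + H]
            k += H
            b2 = z[k]
            k += 1
            heads.append((W1, b1, w2, b2))
        w = mixing_weights(self.spec, z[k:])
        return heads, w

    def network(self, Q: np.ndarray, z: np.ndarray | None = None,
                head: int = 0):
        """Forward pass of one head: site values U and gradients dU/dq for
        descriptor rows Q.

        ``head`` 0 is the pair head (its gradients build partial forces);
        head 1 (rank-2 only) is the scalar head whose values feed the
        isotropic term.  Standardization, when present, is applied inside:
        the returned gradient is with respect to the raw descriptor.
        """
        heads, _ = self._split(z)
        W1, b1, w2, b2 = heads[head]
        if self.q_shift is not None:
            Q = Q - self.q_shift
        if self.q_scale is not None:
            Q = Q / self.q_scale
        H = np.tanh(Q @ W1.T + b1)
        U = H @ w2 + b2
        dU_dq = ((1.0 - H * H) * w2) @ W1
        if self.q_scale is not None:
            dU_dq = dU_dq / self.q_scale
        return U, dU_dq


def initial_parameters(spec: DescriptorSpec, n_neurons: int,
                       seed: int | None = None,
                       scale: float = 0.0, n_heads: int = 1) -> np.ndarray:
    """A starting parameter vector: network blocks of given scale (zeros by
    default), mixing weights at 1 so species are initially undistinguished.

    ``n_heads`` is 1 for dipole models and 2 for rank-2 models.
    """
    n_net = n_heads * ((spec.length + 2) * n_neurons + 1)
    rng = np.random.default_rng(seed)
    net = scale * rng.standard_normal(n_net) if scale else np.zeros(n_net)
    return np.concatenate([net, np.ones(spec.n_mixing)])


def _evaluate(model: TensorModel, structure: AtomicStructure,
              ctx: DescriptorContext | None = None):
    """Common machinery: context, descriptors, pair-head site values and
    partial forces per pair."""
    if ctx is None:
        ctx = DescriptorContext(structure, model.spec)
    _, w = model._split()
    Q = ctx.descriptors(w)
    U, dU_dq = model.network(Q)
    dQ = ctx.pair_gradients(w)  # (P, D, 3)
    if len(ctx.pair_i):
        F = np.einsum("pd,pdx->px", dU_dq[ctx.pair_i], dQ)
    else:
        F = np.zeros((0, 3))
    return ctx, Q, U, F


def site_values(model: TensorModel, structure: AtomicStructure,
                head: int = 0) -> np.ndarray:
    """Per-atom scalars U_i (model units).

    ``head`` 0 is the pair head (the one partial forces differentiate);
    ``head`` 1, available on rank-2 models, is the scalar head feeding the
    isotropic term.
    """
    ctx, Q, U, _ = _evaluate(model, structure)
    if head == 0:
        return U
    return model.network(Q, head=head)[0]


def partial_forces(model: TensorModel, structure: AtomicStructure):
    """Partial forces dU_i/dr_ij.

    Returns ``(table, forces)``: the neighbor table and an aligned
    (n_pairs, 3) array.  For finite systems ``as_partial_force_dict`` turns
    this into a {(i, j): vector} map.
    """
    ctx, _, _, F = _evaluate(model, structure)
    return ctx.table, F


def as_partial_force_dict(table, forces) -> dict:
    """Map (i, j) -> dU_i/dr_ij for tables without repeated images."""
    out = {}
    for p in range(table.n_pairs):
        key = (int(table.i_idx[p]), int(table.j_idx[p]))
        if key in out:
            raise ValueError(
                "pair appears through multiple images; use the array form"
            )
        out[key] = forces[p]
    return out


def predict_rank1(model: TensorModel, structure: AtomicStructure) -> np.ndarray:
    """Dipole moment mu (e*bohr): contraction of the virial-form tensor with r_ij."""
    if model.kind != "dipole":
        raise ValueError(f"rank-1 prediction needs a dipole model, got {model.kind}")
    ctx, _, _, F = _evaluate(model, structure)
    if not len(ctx.pair_i):
        return np.zeros(3)
    d2 = ctx.pair_d ** 2
    if model.contraction == "first":
        # mu^v = sum_p (r_p . r_p) F_p^v
        return d2 @ F
    # 'second': contract over the partial-force index instead
    return (np.einsum("px,px->p", ctx.pair_r, F)[:, None] * ctx.pair_r).sum(0)


def virial_form(model: TensorModel, structure: AtomicStructure) -> np.ndarray:
    """Unsymmetrized pair tensor W^{uv} = sum r_ij^u dU_i/dr_ij^v."""
    ctx, _, _, F = _evaluate(model, structure)
    if not len(ctx.pair_i):
        return np.zeros((3, 3))
    return np.einsum("pu,pv->uv", ctx.pair_r, F)


def predict_rank2(model: TensorModel, structure: AtomicStructure) -> np.ndarray:
    """Symmetric polarizability/susceptibility tensor.

    alpha^{uv} = delta^{uv} sum_i U_i + sym[sum r_ij^u dU_i/dr_ij^v]; only
    the pair term feeds the off-diagonal elements.
    """
    if model.kind not in ("polarizability", "susceptibility"):
        raise ValueError(
            f"rank-2 prediction needs a polarizability/susceptibility model, "
            f"got {model.kind}"
        )
    if model.kind == "susceptibility" and not any(structure.pbc):
        raise ValueError("susceptibility is defined for periodic structures only")
    ctx, Q, _, F = _evaluate(model, structure)
    U_iso = model.network(Q, head=1)[0]
    if len(ctx.pair_i):
        W = np.einsum("pu,pv->uv", ctx.pair_r, F)
    else:
        W = np.zeros((3, 3))
    return np.eye(3) * U_iso.sum() + 0.5 * (W + W.T)


def predict(model: TensorModel, structure: AtomicStructure) -> np.ndarray:
    """Rank-appropriate prediction (3-vector or symmetric 3x3)."""
    if model.rank == 1:
        return predict_rank1(model, structure)
    return predict_rank2(model, structure)


# ---------------------------------------------------------------------------
# plain-text serialization

def save_model(model: TensorModel, path) -> None:
    """Write a versioned plain-text model file (one parameter per line)."""
    s = model.spec
    with open(path, "w") as fh:
        fh.write(f"{MODEL_FORMAT} v{MODEL_VERSION}\n")
        fh.write(f"kind {model.kind}\n")
        fh.write(f"species {s.n_species} " + " ".join(s.species) + "\n")
        fh.write(f"cutoff {s.r_cut_radial:.12g} {s.r_cut_angular:.12g}\n")
        fh.write(f"n_max {s.n_max_radial} {s.n_max_angular}\n")
        fh.write(f"l_max {s.l_max}\n")
        fh.write(f"neurons {model.n_neurons}\n")
        fh.write(f"contraction {model.contraction}\n")
        fh.write(f"mixing {1 if s.trainable_pair_mixing else 0}\n")
        fh.write(f"per_atom_normalized {1 if model.per_atom_normalized else 0}\n")
        if model.q_shift is not None:
            fh.write("q_shift " + " ".join(repr(float(v)) for v in model.q_shift) + "\n")
        if model.q_scale is not None:
            fh.write("q_scale " + " ".join(repr(float(v)) for v in model.q_scale) + "\n")
        fh.write(f"parameters {len(model.z)}\n")
        for v in model.z:
            fh.write(repr(float(v)) + "\n")


def load_model(path, expected_kind: str | None = None) -> TensorModel:
    """Read a model file; round-trips through save_model bit-identically."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(MODEL_FORMAT):
        raise ModelFormatError(f"not a {MODEL_FORMAT} file: {path}")
    version = lines[0].split("v")[-1]
    if int(version) != MODEL_VERSION:
        raise ModelFormatError(f"unsupported model version {version}")
    head = {}
    k = 1
    while k < len(lines):
        parts = lines[k].split()
        head[parts[0]] = parts[1:]
        k += 1
        if parts[0] == "parameters":
            break
    required = ["kind", "species", "cutoff", "n_max", "l_max", "neurons",
                "contraction", "mixing", "per_atom_normalized", "parameters"]
    for key in required:
        if key not in head:
            raise ModelFormatError(f"model file missing header field {key!r}")
    kind = head["kind"][0]
    if expected_kind is not None and kind != expected_kind:
        raise ModelFormatError(
            f"model kind {kind!r} does not match requested {expected_kind!r}"
        )
    nsp = int(head["species"][0])
    species = head["species"][1:]
    if len(species) != nsp:
        raise ModelFormatError("species count mismatch in header")
    spec = DescriptorSpec(
        r_cut_radial=float(head["cutoff"][0]),
        r_cut_angular=float(head["cutoff"][1]),
        n_max_radial=int(head["n_max"][0]),
        n_max_angular=int(head["n_max"][1]),
        l_max=int(head["l_max"][0]),
        species=species,
        trainable_pair_mixing=bool(int(head["mixing"][0])),
    )
    n_params = int(head["parameters"][0])
    z = np.array([float(v) for v in lines[k:]])
    if len(z) != n_params:
        raise ModelFormatError(
            f"model file declares {n_params} parameters but contains {len(z)}"
        )
    return TensorModel(
        kind=kind,
        spec=spec,
        n_neurons=int(head["neurons"][0]),
        z=z,
        per_atom_normalized=bool(int(head["per_atom_normalized"][0])),
        contraction=head["contraction"][0],
        q_shift=(np.array([float(v) for v in head["q_shift"]])
                 if "q_shift" in head else None),
        q_scale=(np.array([float(v) for v in head["q_scale"]])
                 if "q_scale" in head else None),
    )
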
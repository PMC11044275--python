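"""Extended-XYZ structure files and columnar tensor trajectories.

The on-disk dialect: per-structure tensors live in the extended-XYZ comment
line as ``dipole="dx dy dz"`` (e*bohr) and ``pol="a11 a12 ... a33"``
(row-major, bohr^3); the susceptibility uses ``sus=...`` with the same
layout.  Key names are remappable through ``label_key_map`` to tolerate
dataset dialects.  Positions and lattice vectors are Angstrom, floats are
written with 12 significant digits.
"""

from __future__ import annotations

import re

import numpy as np

from .structures import AtomicStructure, TensorTrajectory

DEFAULT_LABEL_KEYS = {"dipole": "dipole", "polarizability": "pol", "susceptibility": "sus"}

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


class ExtxyzParseError(ValueError):
    """Malformed extended-XYZ input; the message names the offending line."""


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _floats(text: str, n: int, what: str, lineno: int) -> np.ndarray:
    parts = text.split()
    if len(parts) != n:
        raise ExtxyzParseError(
            f"line {lineno}: {what} needs {n} numbers, got {len(parts)}"
        )
    try:
        return np.array([float(p) for p in parts])
    except ValueError as exc:
        raise ExtxyzParseError(f"line {lineno}: bad number in {what}: {exc}")


def read_extxyz(path, label_key_map: dict[str, str] | None = None) -> list[AtomicStructure]:
    """Read all frames of an extended-XYZ file.

    Rank-2 labels are symmetrized as (A + A^T)/2; an asymmetry above 1e-3
    raises.  Missing labels stay absent (never zero-filled).  Atom order is
    preserved exactly.
    """
    keys = dict(DEFAULT_LABEL_KEYS)
    if label_key_map:
        keys.update(label_key_map)
    with open(path) as fh:
        lines = fh.read().splitlines()
    structures = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ExtxyzParseError(
                f"line {ln + 1}: expected atom count, got {lines[ln]!r}"
            )
        if natoms < 1:
            raise ExtxyzParseError(f"line {ln + 1}: atom count must be >= 1")
        if ln + 1 >= len(lines):
            raise ExtxyzParseError(f"line {ln + 1}: missing comment line")
        if ln + 2 + natoms > len(lines):
            raise ExtxyzParseError(
                f"line {ln + 1}: frame declares {natoms} atoms but file ends early"
            )
        comment = lines[ln + 1]
        fields = _parse_comment(comment)
        cell = None
        pbc = (False, False, False)
        if "Lattice" in fields:
            cell = _floats(fields["Lattice"], 9, "Lattice", ln + 2).reshape(3, 3)
        if "pbc" in fields:
            flags = fields["pbc"].split()
            if len(flags) != 3:
                raise ExtxyzParseError(f"line {ln + 2}: pbc needs three flags")
            pbc = tuple(f in ("T", "True", "true", "1") for f in flags)
        elif cell is not None:
            pbc = (True, True, True)
        species, positions = [], []
        for k in range(natoms):
            lineno = ln + 3 + k
            parts = lines[ln + 2 + k].split()
            if len(parts) < 4:
                raise ExtxyzParseError(
                    f"line {lineno}: atom line needs symbol + 3 coordinates"
                )
            species.append(parts[0])
            try:
                positions.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise ExtxyzParseError(f"line {lineno}: bad coordinate: {exc}")
        kwargs = {}
        if keys["dipole"] in fields:
            kwargs["dipole"] = _floats(
                fields[keys["dipole"]], 3, "dipole", ln + 2
            )
        for kind in ("polarizability", "susceptibility"):
            if keys[kind] in fields:
                kwargs[kind] = _floats(
                    fields[keys[kind]], 9, kind, ln + 2
                ).reshape(3, 3)
        if "weight" in fields:
            kwargs["weight"] = float(fields["weight"])
        structures.append(
            AtomicStructure(species, np.array(positions), cell=cell, pbc=pbc, **kwargs)
        )
        ln += 2 + natoms
    return structures


def _fmt(x: float) -> str:
    # shortest representation that round-trips the float64 exactly
    return repr(float(x))


def write_extxyz(structures, path, label_key_map: dict[str, str] | None = None) -> None:
    """Write structures in extended-XYZ; re-readable with loss < 1e-12 per field."""
    keys = dict(DEFAULT_LABEL_KEYS)
    if label_key_map:
        keys.update(label_key_map)
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            parts = []
            if s.cell is not None:
                parts.append('Lattice="' + " ".join(_fmt(v) for v in s.cell.ravel()) + '"')
            parts.append("Properties=species:S:1:pos:R:3")
            if any(s.pbc) or s.cell is not None:
                parts.append('pbc="' + " ".join("T" if b else "F" for b in s.pbc) + '"')
            if s.dipole is not None:
                parts.append(f'{keys["dipole"]}="' + " ".join(_fmt(v) for v in s.dipole) + '"')
            if s.polarizability is not None:
                parts.append(
                    f'{keys["polarizability"]}="'
                    + " ".join(_fmt(v) for v in s.polarizability.ravel()) + '"'
                )
            if s.susceptibility is not None:
                parts.append(
                    f'{keys["susceptibility"]}="'
                    + " ".join(_fmt(v) for v in s.susceptibility.ravel()) + '"'
                )
            if s.weight != 1.0:
                parts.append(f"weight={_fmt(s.weight)}")
            fh.write(" ".join(parts) + "\n")
            for sym, pos in zip(s.species, s.positions):
                fh.write(f"{sym} " + " ".join(_fmt(v) for v in pos) + "\n")


def read_trajectory(path, dt: float | None = None, rank: int = 1,
                    label_key_map: dict[str, str] | None = None,
                    kind: str | None = None) -> TensorTrajectory:
    """Read a tensor time series.

    Two layouts are accepted:

    * an extended-XYZ frame sequence whose comment lines carry the tensor
      label (``dt`` must then be supplied);
    * a whitespace-separated columnar file with a time column (fs) followed
      by 3 (rank 1) or 9 (rank 2, row-major) values per line.

    Columnar time stamps must be uniformly spaced to 1e-6 relative; a
    supplied ``dt`` must agree with the file's spacing.
    """
    with open(path) as fh:
        first = fh.readline().split()
    is_extxyz = len(first) == 1
    if is_extxyz:
        if dt is None:
            raise ValueError("dt is required for extended-XYZ trajectories")
        structures = read_extxyz(path, label_key_map)
        if kind is None:
            kind = "dipole" if rank == 1 else "polarizability"
        frames = []
        for i, s in enumerate(structures):
            lab = s.label(kind)
            if lab is None and rank == 2 and kind == "polarizability":
                lab = s.label("susceptibility")
            if lab is None:
                raise ValueError(f"frame {i} carries no {kind} label")
            want = 1 if lab.ndim == 1 else 2
            if want != rank:
                raise ValueError(
                    f"frame {i}: label rank {want} does not match requested rank {rank}"
                )
            frames.append(lab)
        return TensorTrajectory(dt=dt, frames=np.array(frames), rank=rank)
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    ncols = 1 + (3 if rank == 1 else 9)
    if data.shape[1] != ncols:
        raise ValueError(
            f"rank-{rank} columnar trajectory needs {ncols} columns, "
            f"got {data.shape[1]}"
        )
    t = data[:, 0]
    steps = np.diff(t)
    if len(steps) < 1:
        raise ValueError("trajectory needs at least 2 frames")
    step = steps[0]
    if step <= 0 or np.max(np.abs(steps - step)) > 1e-6 * abs(step):
        raise ValueError(
            "nonuniform time spacing (beyond 1e-6 relative); resample first"
        )
    if dt is not None and abs(dt - step) > 1e-6 * step:
        raise ValueError(f"requested dt={dt} disagrees with file spacing {step}")
    vals = data[:, 1:]
    frames = vals if rank == 1 else vals.reshape(-1, 3, 3)
    return TensorTrajectory(dt=float(step), frames=frames, rank=rank)


def write_trajectory(traj: TensorTrajectory, path, header: str | None = None) -> None:
    """Write a trajectory in the columnar layout accepted by read_trajectory."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for k, frame in enumerate(traj.frames):
            vals = frame.ravel()
            fh.write(_fmt(k * traj.dt) + " " + " ".join(_fmt(v) for v in vals) + "\n")
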
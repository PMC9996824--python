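"""Trajectory containers, file I/O and atom selections.

Coordinates are stored in Angstrom as a dense ``(n_frames, n_atoms, 3)``
array together with a flat per-atom topology.  Multi-model PDB is the
canonical interchange format; XYZ and binary trajectories (DCD/XTC with a
PDB topology) are read through the same interface.  File parsing and
writing are delegated to MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "Topology",
    "AtomSelection",
    "TrajectoryError",
    "TrajectoryParseError",
    "StructuralError",
    "SelectionError",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
]

#: Atom names treated as protein backbone.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class TrajectoryError(Exception):
    """Base class for trajectory handling errors."""


class TrajectoryParseError(TrajectoryError):
    """A file could not be parsed under the named format."""


class StructuralError(TrajectoryError):
    """Frames of one file disagree structurally (e.g. atom counts)."""


class SelectionError(TrajectoryError):
    """A selection expression matched nothing or was malformed."""


def _is_hydrogen(name: str) -> bool:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() == "H"


@dataclass
class Topology:
    """Per-atom metadata: names, residue assignment and element class."""

    atom_names: np.ndarray        # (n_atoms,) str
    residue_indices: np.ndarray   # (n_atoms,) int, 0-based, contiguous
    residue_names: np.ndarray     # (n_atoms,) str
    backbone: np.ndarray = None   # (n_atoms,) bool
    heavy: np.ndarray = None      # (n_atoms,) bool

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        if self.backbone is None:
            self.backbone = np.array(
                [n in BACKBONE_NAMES for n in self.atom_names], dtype=bool
            )
        else:
            self.backbone = np.asarray(self.backbone, dtype=bool)
        if self.heavy is None:
            self.heavy = np.array(
                [not _is_hydrogen(n) for n in self.atom_names], dtype=bool
            )
        else:
            self.heavy = np.asarray(self.heavy, dtype=bool)
        uniq = np.unique(self.residue_indices)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise StructuralError(
                "residue indices must be contiguous from 0; "
                f"got {uniq[:10].tolist()}..."
            )

    @property
    def n_atoms(self) -> int:
        return self.atom_names.size

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) + 1 if self.n_atoms else 0


@dataclass
class Trajectory:
    """A sampled conformational ensemble of one condition.

    Parameters
    ----------
    coordinates
        ``(n_frames, n_atoms, 3)`` positions in Angstrom.
    topology
        Per-atom metadata aligned with the second axis.
    frame_interval_ns
        Time between stored frames (metadata only).
    condition_label
        Free-text condition tag, e.g. ``"wild-type"`` or ``"I335H"``.
    """

    coordinates: np.ndarray
    topology: Topology
    frame_interval_ns: float | None = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructuralError(
                f"coordinates must be (frames, atoms, 3); got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 2:
            raise StructuralError("a trajectory needs at least 2 frames")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coordinates).all():
            raise StructuralError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues


@dataclass(frozen=True)
class AtomSelection:
    """Resolved, order-preserving list of 0-based atom indices."""

    indices: tuple

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise SelectionError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"pdb", "ent"}:
        return "pdb"
    if suffix in {"xyz", "dcd", "xtc", "trr"}:
        return suffix
    raise TrajectoryParseError(f"cannot infer trajectory format from {path.name!r}")


def _universe_to_trajectory(u, condition_label: str = "") -> Trajectory:
    import MDAnalysis  # noqa: F401  (imported lazily; heavy)

    atoms = u.atoms
    n_atoms = len(atoms)
    if n_atoms == 0:
        raise TrajectoryParseError("file contains no atoms")
    frames = []
    for ts in u.trajectory:
        if ts.positions.shape[0] != n_atoms:
            raise StructuralError(
                f"frame {ts.frame} has {ts.positions.shape[0]} atoms, expected {n_atoms}"
            )
        frames.append(ts.positions.astype(float).copy())
    if len(frames) < 2:
        raise StructuralError(f"expected >=2 frames, found {len(frames)}")
    # remap residue indices to contiguous 0-based
    resindices = np.asarray(atoms.resindices, dtype=int)
    _, contiguous = np.unique(resindices, return_inverse=True)
    try:
        resnames = np.asarray(atoms.resnames, dtype=object)
    except Exception:
        resnames = np.array(["UNK"] * n_atoms, dtype=object)
    topo = Topology(
        atom_names=np.asarray(atoms.names, dtype=object),
        residue_indices=contiguous,
        residue_names=resnames,
    )
    return Trajectory(
        coordinates=np.stack(frames),
        topology=topo,
        condition_label=condition_label,
    )


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology_path: str | Path | None = None,
    condition_label: str = "",
) -> Trajectory:
    """Read a trajectory from a multi-model PDB, XYZ, or binary file.

    Binary trajectory formats (DCD/XTC) require ``topology_path``
    pointing to a PDB that defines the atoms.

    Raises
    ------
    TrajectoryParseError
        If the file is missing or cannot be parsed under the format.
    StructuralError
        If frames disagree on atom count or fewer than 2 frames exist.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryParseError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt in {"dcd", "xtc", "trr"}:
                if topology_path is None:
                    raise TrajectoryParseError(
                        f"{fmt.upper()} trajectories need a PDB topology (topology_path)"
                    )
                u = mda.Universe(str(topology_path), str(path))
            else:
                u = mda.Universe(str(path), format=fmt)
    except StructuralError:
        raise
    except TrajectoryParseError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of exception types
        msg = str(exc)
        if "atom" in msg.lower() and ("number" in msg.lower() or "count" in msg.lower()):
            raise StructuralError(f"inconsistent atom counts in {path.name}: {msg}")
        raise TrajectoryParseError(f"cannot parse {path.name} as {fmt}: {msg}")
    try:
        return _universe_to_trajectory(u, condition_label=condition_label)
    except StructuralError:
        raise
    except Exception as exc:
        raise StructuralError(f"structural problem in {path.name}: {exc}")


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> Path:
    """Write a Trajectory as multi-model PDB or multi-frame XYZ."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, format)
    topo = traj.topology
    n_res = traj.n_residues
    u = mda.Universe.empty(
        traj.n_atoms,
        n_residues=n_res,
        atom_resindex=topo.residue_indices,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.atom_names.astype(str))
    u.add_TopologyAttr("resnames", [
        str(topo.residue_names[topo.residue_indices == r][0]) for r in range(n_res)
    ])
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    elements = ["H" if _is_hydrogen(str(n)) else "C" for n in topo.atom_names]
    u.add_TopologyAttr("elements", elements)
    u.load_new(traj.coordinates.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return path


def resolve_selection(traj: Trajectory, expr: str) -> AtomSelection:
    """Resolve a selection expression to atom indices.

    The mini-language is a conjunction of clauses joined by ``and``:

    - ``all`` — every atom
    - ``backbone`` — atoms named N, CA, C, O
    - ``heavy`` — non-hydrogen atoms
    - ``residue <i>`` — atoms of 0-based residue ``i`` (ranges ``i-j`` allowed)
    - ``atom <NAME>`` / ``name <NAME>`` — atoms with that name
    - ``resname <RES>`` — atoms in residues with that name

    Commas are treated like ``and``. Resolution depends only on the
    topology, never on frame content, and preserves atom order.
    """
    topo = traj.topology
    mask = np.ones(topo.n_atoms, dtype=bool)
    text = expr.replace(",", " and ")
    clauses = [c.strip() for c in text.split(" and ") if c.strip()]
    if not clauses:
        raise SelectionError(f"empty selection expression: {expr!r}")
    for clause in clauses:
        parts = clause.split()
        key = parts[0].lower()
        if key == "all" and len(parts) == 1:
            continue
        elif key == "backbone" and len(parts) == 1:
            mask &= topo.backbone
        elif key == "heavy" and len(parts) == 1:
            mask &= topo.heavy
        elif key in {"residue", "resid"} and len(parts) == 2:
            spec = parts[1]
            if "-" in spec:
                lo, hi = (int(x) for x in spec.split("-", 1))
                sel = (topo.residue_indices >= lo) & (topo.residue_indices <= hi)
            else:
                sel = topo.residue_indices == int(spec)
            mask &= sel
        elif key in {"atom", "name"} and len(parts) == 2:
            mask &= np.array([str(n) == parts[1] for n in topo.atom_names])
        elif key == "resname" and len(parts) == 2:
            mask &= np.array([str(n) == parts[1] for n in topo.residue_names])
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return AtomSelection(indices=tuple(int(i) for i in indices))
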
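"""Coordinate containers, PDB/XYZ input-output, selection and C4 assembly.

The package works on two lightweight containers: :class:`Structure` (one
conformation) and :class:`Ensemble` (an ordered stack of conformations
sharing a topology).  PDB parsing and writing is delegated to biotite;
these containers only carry what the gating analysis needs: atom names,
elements, residue and chain identity, and Cartesian coordinates in Å.

Residue numbers are 1-based and taken verbatim from the input — the
channel literature cites absolute residue ids (e.g. the constriction
residues 124/129/132), so no renumbering is ever applied.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class TopologyError(ValueError):
    """Raised when conformations that must share a topology do not."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty or refers to missing atoms."""


@dataclass
class Structure:
    """One conformation: per-atom identity plus coordinates (Å)."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.res_names = np.asarray(self.res_names, dtype="U4")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = self.coords.shape[0]
        for name in ("atom_names", "elements", "res_ids", "res_names", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match {n} coordinates")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(
            self.atom_names.copy(), self.elements.copy(), self.res_ids.copy(),
            self.res_names.copy(), self.chain_ids.copy(), self.coords.copy(),
            dict(self.metadata),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        out = self.copy()
        out.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if out.coords.shape[0] != self.n_atoms:
            raise TopologyError("coordinate count differs from topology")
        return out

    def mask(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SelectionError("empty selection")
        return Structure(
            self.atom_names[mask], self.elements[mask], self.res_ids[mask],
            self.res_names[mask], self.chain_ids[mask], self.coords[mask],
            dict(self.metadata),
        )

    def atom_index(
        self,
        chain: str | None = None,
        residues: tuple[int, int] | Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Boolean mask for a (chain, residue-range, name) selection."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if residues is not None:
            if isinstance(residues, tuple) and len(residues) == 2:
                lo, hi = residues
                m &= (self.res_ids >= lo) & (self.res_ids <= hi)
            else:
                m &= np.isin(self.res_ids, np.fromiter(residues, dtype=np.int64))
        if atom_names is not None:
            m &= np.isin(self.atom_names, list(atom_names))
        if heavy_only:
            m &= self.elements != "H"
        return m


def select(
    structure: Structure,
    chain: str | None = None,
    residues: tuple[int, int] | Iterable[int] | None = None,
    atom_names: Iterable[str] | None = None,
    heavy_only: bool = False,
) -> Structure:
    """Subset of a structure, preserving atom order.

    ``residues`` is an inclusive ``(first, last)`` interval or an explicit
    iterable of residue ids.  ``heavy_only`` drops hydrogens (element H).
    Raises :class:`SelectionError` if nothing matches.
    """
    return structure.mask(
        structure.atom_index(chain, residues, atom_names, heavy_only)
    )


@dataclass
class Ensemble:
    """Ordered conformations sharing one topology.

    Coordinates are stored as one ``(n_frames, n_atoms, 3)`` array; frames
    materialise as :class:`Structure` views on demand.  ``labels`` may hold
    one ground-truth gating state per frame.
    """

    topology: Structure
    coords: np.ndarray
    labels: list | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("ensemble coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.labels is not None and len(self.labels) != self.n_frames:
            raise ValueError("labels length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class ChannelSpec:
    """Geometry conventions of the pore and its gates.

    ``channel_range`` is the inclusive residue interval lining the pore;
    ``constriction_residues`` the residues whose side chains gate it;
    ``gate_pairs`` the diametrically opposed chain pairs; and
    ``ionic_diameter`` the unhydrated K+ diameter used as the open/closed
    threshold (Å).
    """

    channel_range: tuple[int, int] = (121, 133)
    constriction_residues: tuple[int, ...] = (124, 129, 132)
    gate_pairs: tuple[tuple[str, str], ...] = (("A", "C"), ("B", "D"))
    ionic_diameter: float = 3.5275

    def __post_init__(self) -> None:
        if self.ionic_diameter <= 0:
            raise ValueError("ionic_diameter must be positive")
        lo, hi = self.channel_range
        for r in self.constriction_residues:
            if not lo <= r <= hi:
                raise ValueError(
                    f"constriction residue {r} outside channel range {lo}-{hi}"
                )
        for a, b in self.gate_pairs:
            if a == b:
                raise ValueError("gate pair chains must be distinct")


# ---------------------------------------------------------------------------
# PDB conversion helpers


def _to_atom_array(structure: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.res_id = structure.res_ids
    arr.res_name = structure.res_names
    arr.chain_id = structure.chain_ids
    arr.hetero = np.zeros(structure.n_atoms, dtype=bool)
    return arr


def _from_atom_array(arr: bst.AtomArray, metadata: dict | None = None) -> Structure:
    elements = np.asarray(arr.element)
    meta = dict(metadata or {})
    # record hydrogen provenance: distance reports must state whether
    # hydrogens participated
    meta.setdefault("hydrogens",
                    "present" if (elements == "H").any() else "absent")
    return Structure(
        np.asarray(arr.atom_name), elements,
        np.asarray(arr.res_id), np.asarray(arr.res_name),
        np.asarray(arr.chain_id), np.asarray(arr.coord, dtype=np.float64),
        meta,
    )


def _check_pdb_lines(path: str) -> None:
    """Pre-validate coordinate columns so errors can name the bad line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: malformed coordinate field on line {lineno}: "
                            f"{line.rstrip()!r}"
                        ) from None


def read_pdb(path: str | os.PathLike, model: int = 1) -> Structure:
    """Read one model of a PDB file.

    Coordinates are Å; residue numbers are kept verbatim; hydrogens are
    retained when present.
    """
    path = os.fspath(path)
    _check_pdb_lines(path)
    try:
        pdb = bpdb.PDBFile.read(path)
        arr = pdb.get_structure(model=model)
    except Exception as exc:  # biotite raises several error types
        raise PDBParseError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return _from_atom_array(arr, {"source": path})


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a single-model PDB file (3-decimal coordinate precision)."""
    pdb = bpdb.PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(os.fspath(path))


def read_ensemble(paths: str | os.PathLike | Sequence[str | os.PathLike]) -> Ensemble:
    """Read an ensemble from a multi-model PDB or a sequence of PDB files.

    Frames are kept in file order; any frame whose atom count differs from
    the first raises :class:`TopologyError`.
    """
    if isinstance(paths, (str, os.PathLike)):
        path = os.fspath(paths)
        _check_pdb_lines(path)
        try:
            pdb = bpdb.PDBFile.read(path)
            stack = pdb.get_structure()  # AtomArrayStack, all models
        except Exception as exc:
            msg = str(exc)
            if "models" in msg or "atoms" in msg:
                raise TopologyError(f"{path}: {msg}") from exc
            raise PDBParseError(f"{path}: {msg}") from exc
        if stack.array_length() == 0:
            raise PDBParseError(f"{path}: no ATOM/HETATM records")
        topo = _from_atom_array(stack[0], {"source": path})
        coords = np.asarray(stack.coord, dtype=np.float64)
        return Ensemble(topo, coords, source=path)

    frames = [read_pdb(p) for p in paths]
    if not frames:
        raise PDBParseError("no input files")
    topo = frames[0]
    for p, f in zip(paths, frames[1:]):
        if f.n_atoms != topo.n_atoms:
            raise TopologyError(
                f"{os.fspath(p)}: {f.n_atoms} atoms, expected {topo.n_atoms}"
            )
    coords = np.stack([f.coords for f in frames])
    return Ensemble(topo, coords, source=";".join(os.fspath(p) for p in paths))


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB file."""
    stack = bst.stack([_to_atom_array(ensemble.frame(i))
                       for i in range(ensemble.n_frames)])
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(os.fspath(path))


# Plain-text XYZ trajectory: per frame, a line with the atom count, a
# comment line, then one "name x y z" line per atom (free whitespace,
# full float precision).  Compact alternative to multi-model PDB.

def write_xyz_traj(ensemble: Ensemble, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\nframe {i}\n")
            for name, xyz in zip(ensemble.topology.atom_names,
                                 ensemble.coords[i]):
                fh.write(f"{name} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def read_xyz_traj(path: str | os.PathLike, topology: Structure) -> Ensemble:
    """Read an XYZ trajectory written by :func:`write_xyz_traj`."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            coords = np.empty((n, 3))
            for j in range(n):
                parts = fh.readline().split()
                coords[j] = [float(x) for x in parts[1:4]]
            frames.append(coords)
    if not frames:
        raise PDBParseError(f"{os.fspath(path)}: empty trajectory")
    coords = np.stack(frames)
    if coords.shape[1] != topology.n_atoms:
        raise TopologyError("trajectory atom count differs from topology")
    return Ensemble(topology, coords, source=os.fspath(path))


def assemble_c4(monomer: Structure, axis: np.ndarray = (0.0, 0.0, 1.0),
                chain_ids: Sequence[str] = ("A", "B", "C", "D")) -> Structure:
    """Build a C4 tetramer from one chain by successive 90° rotations.

    The input must contain exactly one chain; output chains are named
    ``chain_ids`` in rotation order and preserve the monomer atom order.
    """
    chains = monomer.chains
    if len(chains) != 1:
        raise ValueError(f"assemble_c4 expects one chain, got {chains}")
    axis = np.asarray(axis, dtype=np.float64)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("axis must be non-zero")
    axis = axis / nrm

    parts = []
    for k, cid in enumerate(chain_ids):
        rot = Rotation.from_rotvec(axis * (np.pi / 2.0) * k)
        part = monomer.copy()
        part.coords = rot.apply(monomer.coords)
        part.chain_ids = np.full(monomer.n_atoms, cid, dtype="U2")
        parts.append(part)

    out = Structure(
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.elements for p in parts]),
        np.concatenate([p.res_ids for p in parts]),
        np.concatenate([p.res_names for p in parts]),
        np.concatenate([p.chain_ids for p in parts]),
        np.concatenate([p.coords for p in parts]),
        dict(monomer.metadata),
    )
    out.metadata["symmetric_topology"] = "true"
    return out
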
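"""Structure I/O, atom selection, and rigid-body superposition.

Structures are flat, ordered lists of atom records (author residue
numbering, PDB atom names).  Superposition follows the Kabsch/SVD
construction with the reflection fix, and RMSD helpers operate on
explicit paired-residue selections so the caller controls exactly which
atoms enter a comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io import pdbx as _pdbx

from .errors import (
    DegenerateGeometryError,
    DimensionError,
    ModelNotFoundError,
    SelectionError,
    StructureParseError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Superposition",
    "read_structure",
    "write_pdb",
    "kabsch_superpose",
    "backbone_rmsd",
    "BACKBONE_ATOMS",
    "CA_ONLY",
]

#: Full backbone atom-name set.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: Default atom set for "backbone C-alpha" comparisons.
CA_ONLY = ("CA",)


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record.

    Attributes
    ----------
    chain_id : str
        Author chain identifier.
    residue_number : int
        Author residue number (1-based within a chain).
    residue_name : str
        Three-letter residue code.
    atom_name : str
        Standard PDB atom name (e.g. ``"CA"``).
    position : numpy.ndarray
        Cartesian coordinates in Angstrom, shape ``(3,)``.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise DimensionError(
                f"atom position must be a finite 3-vector, got {self.position!r}"
            )
        if not self.atom_name:
            raise StructureParseError("empty atom name")
        object.__setattr__(self, "position", pos)


class Structure:
    """Ordered collection of atom records for one model.

    Selections preserve input order; duplicate ``(chain, residue,
    atom_name)`` combinations within one model are rejected.
    """

    def __init__(self, atoms: Iterable[AtomRecord], model_id: int = 1):
        self.atoms: list[AtomRecord] = list(atoms)
        self.model_id = int(model_id)
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in self._index:
                raise StructureParseError(
                    f"duplicate atom {key} in model {self.model_id}"
                )
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an ``(N, 3)`` array (input order)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_numbers(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_number, None)
        return list(seen)

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> AtomRecord:
        try:
            return self.atoms[self._index[(chain_id, int(residue_number), atom_name)]]
        except KeyError:
            raise SelectionError(
                f"atom {chain_id}:{residue_number}:{atom_name} not present"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, atom_name: str) -> bool:
        return (chain_id, int(residue_number), atom_name) in self._index

    def select(
        self,
        chain_id: str | None = None,
        residues: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> "Structure":
        """Sub-structure by chain, residue set and atom-name set (order kept)."""
        res = None if residues is None else set(int(r) for r in residues)
        names = None if atom_names is None else set(atom_names)
        picked = [
            a
            for a in self.atoms
            if (chain_id is None or a.chain_id == chain_id)
            and (res is None or a.residue_number in res)
            and (names is None or a.atom_name in names)
        ]
        return Structure(picked, model_id=self.model_id)

    def transformed(self, superposition: "Superposition") -> "Structure":
        """Copy with ``superposition`` applied to every atom."""
        new = superposition.apply(self.coords)
        return Structure(
            [
                AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name, p)
                for a, p in zip(self.atoms, new)
            ],
            model_id=self.model_id,
        )


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform ``x -> R x + t`` with its fit RMSD (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tra.shape != (3,):
            raise DimensionError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(rot.T @ rot - np.eye(3))) > 1e-8:
            raise DegenerateGeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise DegenerateGeometryError("improper rotation (reflection)")
        if self.rmsd < 0:
            raise DimensionError("rmsd must be non-negative")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return coords @ self.rotation.T + self.translation


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("data_") or stripped.startswith("#") or "_atom_site" in stripped:
            return "cif"
        return "pdb"
    raise StructureParseError("empty structure text")


def _from_atom_array(arr, model_id: int) -> Structure:
    records = []
    for i in range(arr.array_length()):
        records.append(
            AtomRecord(
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                position=arr.coord[i],
            )
        )
    return Structure(records, model_id=model_id)


def read_structure(text: str, model: int = 1) -> Structure:
    """Parse PDB or mmCIF content into a :class:`Structure`.

    The format is sniffed from the first non-blank line.  All ATOM and
    HETATM records of the requested model are captured; alternate
    locations resolve to the highest-occupancy conformer.

    Raises
    ------
    StructureParseError
        On malformed input (the underlying parser message names the line).
    ModelNotFoundError
        If the requested model is absent.
    """
    fmt = _sniff_format(text)
    try:
        if fmt == "pdb":
            pdb_file = PDBFile.read(io.StringIO(text))
            arr = pdb_file.get_structure(model=model, altloc="occupancy")
        else:
            cif_file = _pdbx.CIFFile.read(io.StringIO(text))
            arr = _pdbx.get_structure(cif_file, model=model, altloc="occupancy")
    except ValueError as exc:
        msg = str(exc)
        if "model" in msg.lower():
            raise ModelNotFoundError(msg) from exc
        raise StructureParseError(msg) from exc
    except Exception as exc:  # pragma: no cover - parser-specific failures
        raise StructureParseError(str(exc)) from exc
    return _from_atom_array(arr, model_id=model)


def write_pdb(structure: Structure) -> str:
    """Serialize a structure to fixed-column PDB text (3-decimal precision)."""
    n = len(structure)
    arr = _struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in structure], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in structure])
    arr.res_name = np.array([a.residue_name for a in structure], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in structure], dtype="U6")
    arr.element = np.array([a.atom_name[:1] for a in structure], dtype="U2")
    arr.coord = structure.coords
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def _as_points(x, name: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DimensionError(f"{name} must be an (N, 3) array, got shape {pts.shape}")
    return pts


def _canonical_order(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Fix operand order so the computation is bitwise symmetric in (p, q).
    if p.tobytes() <= q.tobytes():
        return p, q
    return q, p


def kabsch_superpose(mobile, target) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (reflections are corrected by flipping
    the smallest singular vector) and translation minimizing the RMSD of
    paired points, together with that minimum RMSD.

    Raises
    ------
    DimensionError
        If point counts differ or fewer than 3 pairs are given.
    DegenerateGeometryError
        If either point set is (near-)collinear.
    """
    p = _as_points(mobile, "mobile")
    q = _as_points(target, "target")
    if p.shape != q.shape:
        raise DimensionError(f"point counts differ: {p.shape[0]} vs {q.shape[0]}")
    if p.shape[0] < 3:
        raise DimensionError("need at least 3 point pairs")

    cp = p.mean(axis=0)
    cq = q.mean(axis=0)
    pc = p - cp
    qc = q - cq
    for pts, name in ((pc, "mobile"), (qc, "target")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(1.0, s[0]):
            raise DegenerateGeometryError(f"{name} points are collinear/degenerate")

    # Work on a canonical operand order so rmsd(a, b) == rmsd(b, a)
    # bitwise; the rotation for the original orientation is recovered by
    # transposition when the operands were swapped.
    a, b = _canonical_order(pc, qc)
    swapped = a is not pc
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot_c = vt.T @ flip @ u.T  # maps a onto b
    resid = a @ rot_c.T - b
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    rot = rot_c.T if swapped else rot_c
    tra = cq - rot @ cp
    return Superposition(rotation=rot, translation=tra, rmsd=rmsd)


def gather_paired_coords(
    a: Structure,
    b: Structure,
    selection: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    atoms: Sequence[str] = CA_ONLY,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of ``atoms`` for each paired residue of a selection.

    ``selection`` pairs residues as ``((chain_a, res_a), (chain_b, res_b))``.
    Missing residues or atoms raise :class:`SelectionError` listing every
    absentee.
    """
    missing: list[str] = []
    pa: list[np.ndarray] = []
    pb: list[np.ndarray] = []
    for (ca_id, ra), (cb_id, rb) in selection:
        for name in atoms:
            if not a.has_atom(ca_id, ra, name):
                missing.append(f"a:{ca_id}:{ra}:{name}")
            if not b.has_atom(cb_id, rb, name):
                missing.append(f"b:{cb_id}:{rb}:{name}")
        if missing:
            continue
        for name in atoms:
            pa.append(a.atom(ca_id, ra, name).position)
            pb.append(b.atom(cb_id, rb, name).position)
    if missing:
        raise SelectionError("missing atoms: " + ", ".join(missing))
    return np.asarray(pa), np.asarray(pb)


def backbone_rmsd(
    a: Structure,
    b: Structure,
    selection: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    atoms: Sequence[str] = CA_ONLY,
    fit: str = "local",
) -> float:
    """RMSD over a paired residue selection.

    With ``fit="local"`` (default) the selected atoms themselves are
    best-fit superposed before the RMSD is taken; ``fit="none"`` computes
    the RMSD in the frame the structures are given in (use after a prior
    global superposition).  Symmetric in ``(a, b)``.
    """
    pa, pb = gather_paired_coords(a, b, selection, atoms)
    if fit == "local":
        return kabsch_superpose(pa, pb).rmsd
    if fit == "none":
        return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    raise ValueError(f"fit must be 'local' or 'none', got {fit!r}")


def parse_selection(expr: str) -> list[tuple[str, int]]:
    """Parse ``"chain:start-end"`` (or ``"chain:res"``) into residue tuples.

    Multiple comma-separated ranges are allowed, e.g. ``"A:3-7,A:12"``.
    """
    out: list[tuple[str, int]] = []
    for part in expr.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            chain, rng = part.split(":")
            if "-" in rng:
                lo, hi = rng.split("-")
                out.extend((chain, r) for r in range(int(lo), int(hi) + 1))
            else:
                out.append((chain, int(rng)))
        except ValueError:
            raise SelectionError(f"cannot parse selection {part!r}") from None
    return out
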
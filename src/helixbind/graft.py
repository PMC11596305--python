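"""Binding-site transplantation between the two faces of a pseudosymmetric
four-helix bundle.

The primary receptor-binding site of the template sits on the H2/H3 helix
pair.  Because the bundle's H1/H4 pair is approximately related to H2/H3
by an internal two-fold, the same site can be re-grafted onto H1/H4 in
either a *parallel* orientation (H2->H1 and H3->H4, co-directional
sequence sense) or an *antiparallel* one (same helix pairing, reversed
sequence sense).  Positions are carried over by best-fit superposition of
the source helix pair onto the destination pair followed by nearest-CA
correspondence, optionally shifted along the helices by an integer
register offset chosen to minimize the backbone RMSD of the re-grafted
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    CollisionError,
    NoFeasibleRegisterError,
    RegisterError,
    SelectionError,
)
from .structio import (
    CA_ONLY,
    Structure,
    Superposition,
    backbone_rmsd,
    kabsch_superpose,
)

__all__ = [
    "HelixSegment",
    "HelixAnnotation",
    "BindingSite",
    "GraftSpec",
    "GraftResult",
    "PositionMapping",
    "TernaryComplex",
    "SpacingEstimate",
    "map_pseudosymmetric_positions",
    "optimize_register",
    "apply_graft",
    "assess_graft_sites",
    "inter_tmd_spacing",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HelixSegment:
    """One helix: chain, inclusive residue range, and axial direction."""

    chain: str
    start: int
    end: int
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 6:
            raise ValueError(f"helix {self.chain}:{self.start}-{self.end} shorter than 6 residues")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class HelixAnnotation:
    """The four helices H1..H4, ordered by sequence, non-overlapping."""

    h1: HelixSegment
    h2: HelixSegment
    h3: HelixSegment
    h4: HelixSegment

    def __post_init__(self) -> None:
        segs = self.helices
        for a, b in zip(segs, segs[1:]):
            if a.chain == b.chain and b.start <= a.end:
                raise ValueError("helix segments overlap or are out of sequence order")

    @property
    def helices(self) -> tuple[HelixSegment, HelixSegment, HelixSegment, HelixSegment]:
        return (self.h1, self.h2, self.h3, self.h4)

    def helix_of(self, chain: str, residue: int) -> HelixSegment | None:
        for seg in self.helices:
            if seg.chain == chain and residue in seg:
                return seg
        return None


@dataclass(frozen=True)
class BindingSite:
    """Ordered site definition: residue positions plus target amino acids."""

    role: str  # "primary" | "secondary"
    entries: tuple[tuple[int, str], ...]
    reference: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("primary", "secondary"):
            raise ValueError("role must be 'primary' or 'secondary'")
        entries = tuple((int(p), str(a)) for p, a in self.entries)
        positions = [p for p, _ in entries]
        if len(set(positions)) != len(positions):
            raise ValueError("binding-site positions must be unique")
        for _, aa in entries:
            if aa not in AA_ALPHABET:
                raise ValueError(f"unknown amino acid {aa!r}")
        object.__setattr__(self, "entries", entries)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.entries)


@dataclass(frozen=True)
class GraftSpec:
    """User-facing graft request (canonical patch sizes only)."""

    orientation: str
    patch_size: int
    register_offset: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError("orientation must be 'parallel' or 'antiparallel'")
        if self.patch_size not in (12, 15, 17):
            raise ValueError("patch_size must be one of 12, 15, 17")


@dataclass(frozen=True)
class PositionMapping:
    """Bijective source->destination residue map plus the transform used."""

    mapping: tuple[tuple[tuple[str, int], tuple[str, int]], ...]
    superposition: Superposition
    orientation: str
    register_offset: int

    def as_dict(self) -> dict[tuple[str, int], tuple[str, int]]:
        return dict(self.mapping)

    def inverse(self) -> dict[tuple[str, int], tuple[str, int]]:
        return {dst: src for src, dst in self.mapping}


@dataclass(frozen=True)
class GraftResult:
    mutated_sequence: str
    mapping: tuple[tuple[int, int], ...]
    site_rmsd_primary: float | None = None
    site_rmsd_secondary: float | None = None


def _helix_ca(structure: Structure, seg: HelixSegment) -> tuple[list[int], np.ndarray]:
    residues = [r for r in seg.residues if structure.has_atom(seg.chain, r, "CA")]
    if len(residues) < len(seg) :
        missing = sorted(set(seg.residues) - set(residues))
        raise SelectionError(f"helix {seg.chain}:{seg.start}-{seg.end} missing CA for residues {missing}")
    coords = np.stack([structure.atom(seg.chain, r, "CA").position for r in residues])
    return residues, coords


def _pair_superposition(
    structure: Structure, annotation: HelixAnnotation, orientation: str
) -> Superposition:
    """Best-fit transform of the H2/H3 CA trace onto H1/H4."""
    h1, h2, h3, h4 = annotation.helices
    mob: list[np.ndarray] = []
    tgt: list[np.ndarray] = []
    for src_seg, dst_seg in ((h2, h1), (h3, h4)):
        _, src_xyz = _helix_ca(structure, src_seg)
        _, dst_xyz = _helix_ca(structure, dst_seg)
        if orientation == "antiparallel":
            dst_xyz = dst_xyz[::-1]
        m = min(len(src_xyz), len(dst_xyz))
        mob.append(src_xyz[:m])
        tgt.append(dst_xyz[:m])
    return kabsch_superpose(np.concatenate(mob), np.concatenate(tgt))


def map_pseudosymmetric_positions(
    structure: Structure,
    annotation: HelixAnnotation,
    orientation: str,
    register_offset: int = 0,
    positions: Sequence[tuple[str, int]] | None = None,
    cutoff: float = 3.5,
) -> PositionMapping:
    """Map residue positions from the H2/H3 face onto the H1/H4 face.

    The source helix pair is superposed onto the destination pair with a
    sequence-sense pairing fixed by ``orientation``; each source CA is
    then assigned to its nearest destination CA (within ``cutoff``
    Angstrom) and shifted along the destination helix by
    ``register_offset`` residues.

    Parameters
    ----------
    positions
        Source positions to map, as ``(chain, residue)``.  Defaults to
        every residue of H2 and H3.

    Raises
    ------
    RegisterError
        If the offset pushes a mapped position outside its helix.
    CollisionError
        If two source positions land on the same destination.
    SelectionError
        If a source CA finds no destination CA within ``cutoff``.
    """
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError("orientation must be 'parallel' or 'antiparallel'")
    h1, h2, h3, h4 = annotation.helices
    sup = _pair_superposition(structure, annotation, orientation)

    dst_res: list[tuple[str, int]] = []
    dst_xyz: list[np.ndarray] = []
    dst_seg_of: dict[tuple[str, int], HelixSegment] = {}
    for seg in (h1, h4):
        residues, xyz = _helix_ca(structure, seg)
        for r, c in zip(residues, xyz):
            dst_res.append((seg.chain, r))
            dst_xyz.append(c)
            dst_seg_of[(seg.chain, r)] = seg
    dst_arr = np.stack(dst_xyz)

    if positions is None:
        positions = [(seg.chain, r) for seg in (h2, h3) for r in seg.residues]
    else:
        positions = [(c, int(r)) for c, r in positions]
        for c, r in positions:
            seg = annotation.helix_of(c, r)
            if seg not in (h2, h3):
                raise SelectionError(f"source position {c}:{r} is not on H2 or H3")

    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    used: dict[tuple[str, int], tuple[str, int]] = {}
    for chain, res in positions:
        moved = sup.apply(structure.atom(chain, res, "CA").position)[0]
        dists = np.linalg.norm(dst_arr - moved, axis=1)
        i = int(np.argmin(dists))
        if dists[i] > cutoff:
            raise SelectionError(
                f"source CA {chain}:{res} has no destination CA within {cutoff} A "
                f"(nearest at {dists[i]:.2f} A)"
            )
        dchain, dres = dst_res[i]
        seg = dst_seg_of[(dchain, dres)]
        shifted = dres + int(register_offset)
        if shifted not in seg:
            raise RegisterError(
                f"offset {register_offset} pushes {dchain}:{dres} outside helix "
                f"{seg.chain}:{seg.start}-{seg.end}"
            )
        dst = (dchain, shifted)
        if dst in used:
            raise CollisionError(
                f"destination {dst} claimed by both {used[dst]} and {(chain, res)}"
            )
        used[dst] = (chain, res)
        pairs.append(((chain, res), dst))
    return PositionMapping(
        mapping=tuple(pairs),
        superposition=sup,
        orientation=orientation,
        register_offset=int(register_offset),
    )


def optimize_register(
    structure: Structure,
    annotation: HelixAnnotation,
    site: BindingSite,
    orientation: str,
    half_width: int = 4,
    reference_coords: np.ndarray | None = None,
    chain: str | None = None,
) -> tuple[int, float]:
    """Exhaustive register scan minimizing the re-grafted site RMSD.

    For each offset in ``[-half_width, half_width]`` the site's source
    positions are mapped to the destination face and the destination CA
    geometry is compared (best-fit RMSD) against the reference site
    geometry.  ``reference_coords`` defaults to the bundle's own CA
    coordinates at the site's source positions.  Ties break toward
    smaller ``|offset|``, then toward the negative offset.
    """
    chain = chain or annotation.h2.chain
    src_positions = [(chain, p) for p in site.positions]
    if reference_coords is None:
        reference_coords = np.stack(
            [structure.atom(c, r, "CA").position for c, r in src_positions]
        )
    reference_coords = np.asarray(reference_coords, dtype=float)

    candidates: list[tuple[float, int]] = []
    for offset in range(-half_width, half_width + 1):
        try:
            pm = map_pseudosymmetric_positions(
                structure, annotation, orientation, register_offset=offset,
                positions=src_positions,
            )
        except (RegisterError, CollisionError, SelectionError):
            continue
        dst_xyz = np.stack(
            [structure.atom(c, r, "CA").position for _, (c, r) in pm.mapping]
        )
        rmsd = kabsch_superpose(reference_coords, dst_xyz).rmsd
        candidates.append((rmsd, offset))
    if not candidates:
        raise NoFeasibleRegisterError(
            f"no feasible register offset in [-{half_width}, {half_width}]"
        )
    candidates.sort(key=lambda c: (c[0], abs(c[1]), c[1]))
    best_rmsd, best_offset = candidates[0]
    return best_offset, best_rmsd


def apply_graft(template_sequence: str, entries: Sequence[tuple[int, str]]) -> str:
    """Substitute amino acids at 1-based destination positions.

    Only the listed positions change; length is preserved.  Duplicate
    destination positions raise :class:`CollisionError`.
    """
    seq = list(template_sequence)
    seen: set[int] = set()
    for pos, aa in entries:
        pos = int(pos)
        if not 1 <= pos <= len(seq):
            raise SelectionError(f"position {pos} outside sequence of length {len(seq)}")
        if pos in seen:
            raise CollisionError(f"two substitutions target position {pos}")
        if aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid {aa!r}")
        seen.add(pos)
        seq[pos - 1] = aa
    return "".join(seq)


def assess_graft_sites(
    model: Structure,
    reference: Structure,
    primary_selection: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    secondary_selection: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    atoms: Sequence[str] = CA_ONLY,
    fit: str = "local",
) -> tuple[float, float]:
    """Best-fit RMSD of the primary and secondary sites against a reference."""
    primary = backbone_rmsd(model, reference, primary_selection, atoms=atoms, fit=fit)
    secondary = backbone_rmsd(model, reference, secondary_selection, atoms=atoms, fit=fit)
    return primary, secondary


@dataclass(frozen=True)
class TernaryComplex:
    """A ligand chain bridging two receptor chains in one structure.

    The trans-membrane-proximal anchor of each receptor chain is the CA
    of its most C-terminal resolved residue, unless an explicit anchor
    residue is supplied.
    """

    structure: Structure
    ligand_chain: str
    receptor_chains: tuple[str, str]
    anchor_residues: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.receptor_chains) != 2:
            raise ValueError("exactly two receptor chains required")

    def anchor(self, chain: str) -> np.ndarray:
        if chain not in self.structure.chains():
            raise SelectionError(f"receptor chain {chain!r} absent from structure")
        if self.anchor_residues and chain in self.anchor_residues:
            res = self.anchor_residues[chain]
        else:
            candidates = [
                r for r in self.structure.residue_numbers(chain)
                if self.structure.has_atom(chain, r, "CA")
            ]
            if not candidates:
                raise SelectionError(f"chain {chain!r} has no CA atoms")
            res = max(candidates)
        return self.structure.atom(chain, res, "CA").position

    def anchor_distance(self) -> float:
        a, b = self.receptor_chains
        return float(np.linalg.norm(self.anchor(a) - self.anchor(b)))


@dataclass(frozen=True)
class SpacingEstimate:
    """Per-model receptor anchor distances with ensemble mean and sample SD."""

    distances: tuple[float, ...]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (min(self.distances) - 1e-12 <= self.mean <= max(self.distances) + 1e-12):
            raise ValueError("mean outside distance range")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def inter_tmd_spacing(models: Sequence[TernaryComplex]) -> SpacingEstimate:
    """Ensemble anchor-to-anchor spacing across ternary-complex models."""
    if not models:
        raise ValueError("need at least one model")
    distances = tuple(m.anchor_distance() for m in models)
    mean = float(np.mean(distances))
    sd = 0.0 if len(distances) == 1 else float(np.std(distances, ddof=1))
    return SpacingEstimate(distances=distances, mean=mean, sd=sd)
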
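"""Seeded generators for every synthetic input the pipeline consumes.

* ideal four-helix bundles with exact internal two-fold pseudosymmetry,
* toy ternary complexes with a prescribed receptor anchor spacing,
* combinatorial sequence pools,
* 1:1 binding sensogram series,
* sigmoidal dose-response plates with controls,
* two-channel Brownian membrane fields of monomer/dimer mixtures.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .graft import HelixAnnotation, HelixSegment, TernaryComplex
from .structio import AtomRecord, Structure

__all__ = [
    "BundleSpec",
    "TrajectorySimConfig",
    "TwoChannelField",
    "make_ideal_bundle",
    "make_toy_complex",
    "simulate_two_channel_field",
    "make_sequence_pool",
    "make_sensogram_series",
    "make_dose_response",
]


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an ideal up-down-up-down four-helix bundle.

    The textbook alpha-helix parameters (1.5 A rise per residue, 3.6
    residues per turn, 2.3 A CA radius) are used; ``bundle_radius`` is
    the distance from the bundle axis to each helix axis.
    """

    residues_per_helix: int = 16
    rise_per_residue: float = 1.5
    residues_per_turn: float = 3.6
    ca_radius: float = 2.3
    bundle_radius: float = 7.4
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_helix < 6:
            raise ValueError("need at least 6 residues per helix")


# Approximate cylindrical placement (radius, phase offset, axial offset)
# of backbone atoms relative to the CA trace of an ideal helix.
_BACKBONE_CYL = {
    "N": (1.50, -0.45, -0.90),
    "CA": (2.30, 0.00, 0.00),
    "C": (1.70, 0.47, 0.55),
    "O": (2.00, 0.42, 1.70),
}
# CA radius above is overridden by BundleSpec.ca_radius.

_RES_NAME = "ALA"


def _c2x(p: np.ndarray) -> np.ndarray:
    return p * np.array([1.0, -1.0, -1.0])


def _c2y(p: np.ndarray) -> np.ndarray:
    return p * np.array([-1.0, 1.0, -1.0])


def _c2z(p: np.ndarray) -> np.ndarray:
    return p * np.array([-1.0, -1.0, 1.0])


def make_ideal_bundle(spec: BundleSpec = BundleSpec()) -> tuple[Structure, HelixAnnotation]:
    """Build an ideal bundle whose H1/H4 face is an exact image of H2/H3.

    Helix 2 (axially "down") is generated explicitly with a phase chosen
    so the helix pair carries an exact in-place two-fold; helices 1, 3
    and 4 are its images under the three C2 rotations of a D2 frame.
    Both the parallel (H2->H1, H3->H4, forward sense) and antiparallel
    (reversed sense) face mappings are therefore exact isometries, which
    gives graft operations a ground-truth fixture.
    """
    n = spec.residues_per_helix
    delta = 2.0 * math.pi / spec.residues_per_turn
    # Phase making "rotate 180 deg about the pair axis" reverse each helix
    # onto itself residue-for-residue.
    theta0 = (math.pi - (n - 1) * delta) / 2.0
    d = spec.bundle_radius / math.sqrt(2.0)

    cyl = dict(_BACKBONE_CYL)
    cyl["CA"] = (spec.ca_radius, 0.0, 0.0)

    # H2: "down" helix centered at (-d, +d); template point i sits at
    # angle theta0 + i*delta, axial coordinate descending with i.
    h2_atoms: list[dict] = []
    for i in range(n):
        theta = theta0 + i * delta
        z = spec.rise_per_residue * (i - (n - 1) / 2.0)
        for name, (r, dth, dz) in cyl.items():
            local = np.array(
                [r * math.cos(theta + dth), r * math.sin(theta + dth), z + dz]
            )
            # proper 180-deg rotation about x makes the helix axially "down"
            pt = _c2x(local) + np.array([-d, d, 0.0])
            h2_atoms.append({"i": i, "name": name, "pos": pt})

    ops = {  # helix index -> (symmetry op on H2, direction)
        1: (_c2y, "up"),
        2: (lambda p: p, "down"),
        3: (_c2x, "up"),
        4: (_c2z, "down"),
    }
    records: list[AtomRecord] = []
    segments: list[HelixSegment] = []
    for k in (1, 2, 3, 4):
        op, direction = ops[k]
        start = (k - 1) * n + 1
        for atom in h2_atoms:
            records.append(
                AtomRecord(
                    chain_id=spec.chain_id,
                    residue_number=start + atom["i"],
                    residue_name=_RES_NAME,
                    atom_name=atom["name"],
                    position=op(atom["pos"]),
                )
            )
        segments.append(
            HelixSegment(spec.chain_id, start, start + n - 1, direction)
        )
    annotation = HelixAnnotation(*segments)
    return Structure(records), annotation


def make_toy_complex(
    ligand: Structure,
    anchor_distance: float,
    receptor_chains: tuple[str, str] = ("R", "S"),
    stub_residues: int = 3,
) -> TernaryComplex:
    """Attach two receptor stub chains with an exact anchor spacing.

    The stubs are short CA-only chains placed symmetrically about the
    ligand centroid along x; the CA of each stub's most C-terminal
    residue sits exactly ``anchor_distance`` apart.
    """
    if anchor_distance <= 0:
        raise ValueError("anchor distance must be positive")
    center = ligand.coords.mean(axis=0) if len(ligand) else np.zeros(3)
    atoms = list(ligand.atoms)
    half = anchor_distance / 2.0
    for sign, chain in zip((-1.0, 1.0), receptor_chains):
        for j in range(stub_residues):
            # C-terminal residue of the stub carries the anchor CA and
            # sits exactly at +/- half along x from the ligand centroid.
            offset = (stub_residues - 1 - j) * 3.8
            pos = center + np.array([sign * (half + offset), 0.0, 0.0])
            atoms.append(
                AtomRecord(
                    chain_id=chain,
                    residue_number=j + 1,
                    residue_name="GLY",
                    atom_name="CA",
                    position=pos,
                )
            )
    structure = Structure(atoms)
    ligand_chain = ligand.chains()[0] if len(ligand) else "A"
    return TernaryComplex(
        structure=structure,
        ligand_chain=ligand_chain,
        receptor_chains=tuple(receptor_chains),
    )


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Two-channel Brownian membrane field with a monomer/dimer mixture.

    Frame interval and stack length default to the imaging conditions
    (32 ms per frame, 150 frames).
    """

    n_per_channel: int = 50
    dimer_fraction: float = 0.3
    d_monomer: float = 0.1  # um^2/s
    d_dimer: float = 0.05  # um^2/s
    frame_interval: float = 0.032  # s
    n_frames: int = 150
    precision: float = 0.02  # um localization noise (1 sigma per axis)
    field_size: float = 10.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer fraction must be in [0, 1]")
        if self.d_monomer < 0 or self.d_dimer < 0:
            raise ValueError("diffusion constants must be non-negative")


@dataclass(frozen=True)
class TwoChannelField:
    """Simulated localizations plus ground truth.

    ``localizations_a``/``localizations_b`` have columns
    ``frame, x_um, y_um, emitter_id``; ``dimer_pairs`` lists the
    ground-truth ``(emitter_id_a, emitter_id_b)`` co-diffusing pairs.
    """

    localizations_a: pd.DataFrame
    localizations_b: pd.DataFrame
    dimer_pairs: tuple[tuple[int, int], ...]
    config: TrajectorySimConfig


def _reflect(x: np.ndarray, size: float) -> np.ndarray:
    period = 2.0 * size
    m = np.mod(x, period)
    return np.where(m > size, period - m, m)


def _brownian_paths(
    rng: np.random.Generator, n: int, d: float, cfg: TrajectorySimConfig
) -> np.ndarray:
    """(n, frames, 2) true positions with reflecting boundaries."""
    step_sd = math.sqrt(2.0 * d * cfg.frame_interval)
    start = rng.uniform(0.0, cfg.field_size, size=(n, 1, 2))
    steps = rng.normal(0.0, step_sd, size=(n, cfg.n_frames - 1, 2))
    raw = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    return _reflect(raw, cfg.field_size)


def simulate_two_channel_field(config: TrajectorySimConfig) -> TwoChannelField:
    """Simulate the dual-color co-diffusion experiment.

    Each dimer carries one emitter per channel moving on an identical
    path with ``d_dimer``; monomers diffuse independently per channel
    with ``d_monomer``.  Localization noise is isotropic Gaussian with
    the configured precision, and boundaries reflect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_channel
    n_dimer = int(round(config.dimer_fraction * n))
    n_mono = n - n_dimer

    dimer_paths = _brownian_paths(rng, n_dimer, config.d_dimer, config)
    mono_a = _brownian_paths(rng, n_mono, config.d_monomer, config)
    mono_b = _brownian_paths(rng, n_mono, config.d_monomer, config)

    def observe(paths: np.ndarray, ids: Sequence[int]) -> pd.DataFrame:
        rows = []
        for k, eid in enumerate(ids):
            noisy = paths[k] + rng.normal(0.0, config.precision, size=paths[k].shape)
            for f in range(config.n_frames):
                rows.append((f, noisy[f, 0], noisy[f, 1], eid))
        return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "emitter_id"])

    ids_dimer_a = list(range(n_dimer))
    ids_mono_a = list(range(n_dimer, n))
    ids_dimer_b = list(range(n_dimer))
    ids_mono_b = list(range(n_dimer, n))

    empty = pd.DataFrame(columns=["frame", "x_um", "y_um", "emitter_id"])

    def combine(frames: list[pd.DataFrame]) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else empty.copy()

    loc_a = combine([observe(dimer_paths, ids_dimer_a), observe(mono_a, ids_mono_a)])
    loc_b = combine([observe(dimer_paths, ids_dimer_b), observe(mono_b, ids_mono_b)])

    pairs = tuple(zip(ids_dimer_a, ids_dimer_b))
    return TwoChannelField(
        localizations_a=loc_a.sort_values(["frame", "emitter_id"], ignore_index=True),
        localizations_b=loc_b.sort_values(["frame", "emitter_id"], ignore_index=True),
        dimer_pairs=pairs,
        config=config,
    )


def make_sequence_pool(
    template: str,
    n_variants: int,
    mutable_positions: Sequence[int],
    alphabet: str,
    seed: int = 0,
) -> tuple[str, ...]:
    """Unique variants of ``template`` mutated only at ``mutable_positions``.

    Positions are 1-based.  Raises ``ValueError`` when ``n_variants``
    exceeds the diversity ``len(alphabet) ** len(mutable_positions)``.
    The template's own residues may be drawn when they are in the
    alphabet, so the template itself can be a member of the pool.
    """
    positions = [int(p) for p in mutable_positions]
    for p in positions:
        if not 1 <= p <= len(template):
            raise ValueError(f"mutable position {p} outside template")
    diversity = len(alphabet) ** len(positions)
    if n_variants > diversity:
        raise ValueError(
            f"requested {n_variants} variants exceeds diversity {diversity}"
        )
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    out: dict[str, None] = {}
    if n_variants == 0:
        return ()
    if not positions:
        return (template,)
    # Rejection sampling; enumerate instead when the space is small.
    if diversity <= 10_000:
        import itertools

        combos = list(itertools.product(letters, repeat=len(positions)))
        order = rng.permutation(len(combos))
        for idx in order:
            seq = list(template)
            for p, aa in zip(positions, combos[idx]):
                seq[p - 1] = aa
            out.setdefault("".join(seq), None)
            if len(out) == n_variants:
                break
    else:
        while len(out) < n_variants:
            seq = list(template)
            for p in positions:
                seq[p - 1] = letters[rng.integers(len(letters))]
            out.setdefault("".join(seq), None)
    return tuple(out)


def make_sensogram_series(
    ka: float,
    kd: float,
    rmax: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    t_assoc: float = 180.0,
    t_dissoc: float = 600.0,
):
    """Concentration series of 1:1 sensograms (see ``sprkin``)."""
    from .sprkin import KineticParams, simulate_sensogram

    params = KineticParams(ka=ka, kd=kd, rmax=rmax)
    return [
        simulate_sensogram(
            params, conc, dt=dt, t_assoc=t_assoc, t_dissoc=t_dissoc,
            noise_sd=noise_sd, drift=drift, seed=seed + i,
        )
        for i, conc in enumerate(concentrations)
    ]


def make_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pos_ctrl: int = 3,
    n_neg_ctrl: int = 3,
):
    """One replicate of a sigmoidal plate with positive/negative controls.

    Positive controls sit at the ``top`` plateau, negative controls at
    ``bottom``; ``noise_sd`` is expressed in response units.
    """
    from .doseresp import DoseResponseData, FourPLParams, fourpl_eval

    if noise_sd < 0:
        raise DataError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    params = FourPLParams(bottom=bottom, top=top, ec50=ec50, hill=hill)
    conc = np.asarray(list(concentrations), dtype=float)
    resp = np.array([fourpl_eval(params, c) for c in conc])
    resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    pos = top + rng.normal(0.0, noise_sd, size=n_pos_ctrl)
    neg = bottom + rng.normal(0.0, noise_sd, size=n_neg_ctrl)
    return DoseResponseData(
        concentrations=conc,
        responses=resp,
        positive_controls=pos,
        negative_controls=neg,
    )
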
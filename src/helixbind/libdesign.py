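"""Two-fragment combinatorial library accounting and screening analytics.

A designed sequence pool is split at a fixed boundary into two fragment
pools; re-assembly of any fragment-1 member with any fragment-2 member
gives the library, whose maximum degeneracy is the product of the unique
pool sizes.  Screening analytics cover FACS gate/coverage arithmetic,
OD-normalized plate Z-scores, and per-position consensus tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, PoolError

__all__ = [
    "SequencePool",
    "OligoPools",
    "SortSpec",
    "split_into_fragment_pools",
    "max_degeneracy",
    "mutational_space_size",
    "consensus_counts",
    "consensus_frequencies",
    "plate_zscores",
    "gate_and_coverage",
    "back_translate",
]

# High-usage E. coli codons; used only for emitting DNA-level oligos.
_ECOLI_CODONS = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SequencePool:
    """Unique equal-length sequences plus a fragment boundary.

    Fragment 1 spans positions ``1..boundary`` (1-based, inclusive),
    fragment 2 spans ``boundary+1..end``.
    """

    sequences: tuple[str, ...]
    boundary: int

    def __post_init__(self) -> None:
        if not self.sequences:
            raise PoolError("empty sequence pool")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise PoolError("pool sequences must have equal length")
        if len(set(self.sequences)) != len(self.sequences):
            raise PoolError("pool sequences must be unique")
        if not 1 <= self.boundary < length:
            raise PoolError(
                f"boundary {self.boundary} must lie strictly inside sequences of length {length}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class OligoPools:
    """Unique fragment pools; degeneracy is the pairing count."""

    pool1: tuple[str, ...]
    pool2: tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.pool1) * len(self.pool2)


@dataclass(frozen=True)
class SortSpec:
    """FACS gate and coverage bookkeeping."""

    events: int
    complexity: int
    gate_fraction: float = 0.001
    coverage_factor: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_fraction <= 1.0:
            raise ValueError("gate fraction must be in (0, 1]")
        if self.complexity < 1:
            raise ValueError("library complexity must be >= 1")


def split_into_fragment_pools(pool: SequencePool) -> OligoPools:
    """Split every sequence at the boundary; keep unique fragments.

    First-seen order is preserved, and every input sequence remains
    reconstructible as a pool1 member concatenated with a pool2 member.
    """
    frag1: dict[str, None] = {}
    frag2: dict[str, None] = {}
    for seq in pool.sequences:
        frag1.setdefault(seq[: pool.boundary], None)
        frag2.setdefault(seq[pool.boundary:], None)
    return OligoPools(pool1=tuple(frag1), pool2=tuple(frag2))


def max_degeneracy(pool1_size: int, pool2_size: int) -> int:
    """Number of distinct full-length pairings of the two fragment pools."""
    p1, p2 = int(pool1_size), int(pool2_size)
    if p1 < 0 or p2 < 0:
        raise ValueError("pool sizes must be non-negative")
    return p1 * p2


def mutational_space_size(n_mutable: int = 11, alphabet_size: int = 17) -> int:
    """Exact size of the in-silico mutational space, ``alphabet ** n``."""
    n, k = int(n_mutable), int(alphabet_size)
    if n < 0:
        raise ValueError("n_mutable must be >= 0")
    if k < 1:
        raise ValueError("alphabet_size must be >= 1")
    return k ** n


def consensus_counts(
    sequences: Sequence[str], positions: Sequence[int] | None = None
) -> dict[int, dict[str, int]]:
    """Per-position symbol counts (positions 1-based; default: all)."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise PoolError("sequences must have equal length")
    if positions is None:
        positions = range(1, length + 1)
    table: dict[int, dict[str, int]] = {}
    for p in positions:
        p = int(p)
        if not 1 <= p <= length:
            raise ValueError(f"position {p} outside sequence length {length}")
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[p - 1]] = counts.get(s[p - 1], 0) + 1
        table[p] = counts
    return table


def consensus_frequencies(
    sequences: Sequence[str], positions: Sequence[int] | None = None
) -> dict[int, dict[str, float]]:
    """Per-position symbol frequencies (each column sums to 1)."""
    counts = consensus_counts(sequences, positions)
    n = len(list(sequences))
    return {p: {s: c / n for s, c in col.items()} for p, col in counts.items()}


def plate_zscores(readout: pd.DataFrame) -> pd.DataFrame:
    """OD-normalized luminescence Z-scores per condition.

    ``readout`` needs columns ``well, condition, od600, luminescence``.
    The returned frame adds ``normalized`` (luminescence / OD600),
    ``zscore`` ((normalized - condition mean) / condition sample SD) and
    a boolean ``degenerate`` flag for conditions with zero spread, whose
    z-scores are set to 0.
    """
    required = {"well", "condition", "od600", "luminescence"}
    missing = required - set(readout.columns)
    if missing:
        raise DataError(f"plate readout missing columns: {sorted(missing)}")
    df = readout.copy()
    if (df["od600"] <= 0).any():
        bad = df.loc[df["od600"] <= 0, "well"].tolist()
        raise DataError(f"non-positive OD600 in wells {bad}")
    df["normalized"] = df["luminescence"] / df["od600"]
    df["zscore"] = np.nan
    df["degenerate"] = False
    for _, idx in df.groupby("condition").groups.items():
        vals = df.loc[idx, "normalized"]
        if len(vals) < 2:
            raise DataError("need >= 2 wells per condition for a defined SD")
        sd = vals.std(ddof=1)
        if sd == 0:
            df.loc[idx, "zscore"] = 0.0
            df.loc[idx, "degenerate"] = True
        else:
            df.loc[idx, "zscore"] = (vals - vals.mean()) / sd
    return df


def gate_and_coverage(
    values: Sequence[float], spec: SortSpec
) -> tuple[float, list[int], bool]:
    """Top-fraction gate with tie inclusion plus the coverage check.

    Selects the ``ceil(N * gate_fraction)`` highest values; the threshold
    is the smallest selected value and ties at the threshold are
    included.  ``coverage_ok`` is true when at least
    ``coverage_factor * complexity`` events were screened.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    k = math.ceil(vals.size * spec.gate_fraction)
    threshold = float(np.sort(vals)[::-1][k - 1])
    selected = [int(i) for i in np.nonzero(vals >= threshold)[0]]
    coverage_ok = spec.events >= spec.coverage_factor * spec.complexity
    return threshold, selected, coverage_ok


def back_translate(sequence: str) -> str:
    """Deterministic DNA back-translation (high-usage E. coli codons)."""
    try:
        return "".join(_ECOLI_CODONS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from None
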
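"""Alignment containers, FASTA I/O, gap-threshold trimming and windowed similarity.

Protein multiple sequence alignments are held as equal-length residue rows over
the 20 standard amino acids plus ``X`` (unknown) and ``-`` (gap).  The module
provides the column-level operations the rest of the package builds on:
per-column gap fractions, trimAl-style gap-threshold column trimming (a column
is kept when its non-gap fraction is at least the threshold), Plotcon-style
windowed similarity profiles under a substitution matrix, and mapping of
ungapped reference-residue positions onto alignment columns.

Coordinates: alignment columns are 0-based internally; reference residue
positions are 1-based (the convention of sequence records).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import DataValidationError, RaggedAlignmentError

logger = logging.getLogger("pdzscan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS + UNKNOWN + GAP)
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + UNKNOWN)


@dataclass(frozen=True)
class Sequence:
    """A named residue string (gapped rows allowed inside alignments)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataValidationError("sequence id must be non-empty")
        bad = set(self.residues.upper()) - ALIGNMENT_ALPHABET
        if bad:
            raise DataValidationError(
                f"sequence {self.id!r} contains letters outside the alphabet: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length gapped sequences.

    ``validate=False`` relaxes the ≥2-rows / non-empty / no-all-gap-row checks;
    trimming uses it so that heavily trimmed products keep row correspondence.
    """

    def __init__(self, rows: TypingSequence[Sequence], validate: bool = True):
        rows = list(rows)
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        if validate:
            if len(rows) < 2:
                raise DataValidationError("alignment needs at least 2 rows")
            if not rows[0].residues:
                raise DataValidationError("alignment rows must be non-empty")
            for r in rows:
                if not r.ungapped():
                    raise DataValidationError(f"row {r.id!r} is all gaps")
        self.rows = rows

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> Sequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise DataValidationError(f"unknown sequence id {seq_id!r}")

    def column(self, j: int) -> str:
        if not 0 <= j < self.length:
            raise DataValidationError(f"column {j} out of range 0..{self.length - 1}")
        return "".join(r.residues[j] for r in self.rows)

    def take_columns(self, columns: TypingSequence[int]) -> "Alignment":
        """Sub-alignment restricted to the given columns (order preserved)."""
        for j in columns:
            if not 0 <= j < self.length:
                raise DataValidationError(
                    f"column {j} out of range 0..{self.length - 1}"
                )
        rows = [
            Sequence(r.id, "".join(r.residues[j] for j in columns)) if columns
            else _empty_row(r.id)
            for r in self.rows
        ]
        return Alignment(rows, validate=False)

    def to_array(self) -> np.ndarray:
        """(n_rows, length) array of single-character strings."""
        return np.array([list(r.residues) for r in self.rows], dtype="U1")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and [
            (r.id, r.residues) for r in self.rows
        ] == [(r.id, r.residues) for r in other.rows]

    def __repr__(self) -> str:
        return f"Alignment({self.n_rows} rows x {self.length} columns)"


def _empty_row(seq_id: str) -> Sequence:
    s = Sequence.__new__(Sequence)
    object.__setattr__(s, "id", seq_id)
    object.__setattr__(s, "residues", "")
    return s


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_sequences(source) -> list[Sequence]:
    """Read unaligned sequences from FASTA text, a path, or a handle."""
    handle = _as_handle(source)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise DataValidationError("empty FASTA input")
    seqs = [Sequence(rec.id, str(rec.seq)) for rec in records]
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate ids in FASTA input")
    return seqs


def read_alignment(source) -> Alignment:
    """Read a FASTA alignment; all records must have equal length.

    Residues are upper-cased; rows keep file order.  Unequal record lengths
    raise :class:`RaggedAlignmentError`.
    """
    return Alignment(read_sequences(source))


def write_fasta(seqs: Iterable[Sequence] | Alignment, path) -> None:
    rows = seqs.rows if isinstance(seqs, Alignment) else list(seqs)
    with open(path, "w") as fh:
        for s in rows:
            fh.write(f">{s.id}\n{s.residues}\n")


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    if isinstance(source, Path):
        return open(source)
    if isinstance(source, str):
        if not source or "\n" in source or source.startswith(">"):
            return io.StringIO(source)
        return open(source)
    raise TypeError(f"cannot read FASTA from {type(source).__name__}")


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """Symmetric residue-pair scores (BLOSUM62 by default).

    EMBOSS's EBLOSUM62 carries the same scores as NCBI BLOSUM62, so the
    biopython-shipped copy is the default; custom matrices in the standard
    NCBI/EMBOSS text layout load via :meth:`from_file`.
    """

    name: str
    _scores: dict = field(repr=False)

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        arr = substitution_matrices.load(name)
        return cls._from_biopython(name, arr)

    @classmethod
    def from_file(cls, path) -> "SubstitutionMatrix":
        arr = substitution_matrices.read(str(path))
        return cls._from_biopython(str(path), arr)

    @classmethod
    def _from_biopython(cls, name, arr) -> "SubstitutionMatrix":
        scores = {}
        letters = arr.alphabet
        for a in letters:
            for b in letters:
                scores[(a, b)] = float(arr[a, b])
        m = cls(name=name, _scores=scores)
        m.check_symmetric()
        return m

    def check_symmetric(self) -> None:
        for (a, b), s in self._scores.items():
            if self._scores.get((b, a)) != s:
                raise DataValidationError(
                    f"matrix {self.name} not symmetric at ({a},{b})"
                )

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise DataValidationError(
                f"matrix {self.name} has no score for pair ({a},{b})"
            ) from None

    def as_lookup(self, alphabet: str = AMINO_ACIDS) -> np.ndarray:
        n = len(alphabet)
        out = np.zeros((n, n))
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                out[i, j] = self[(a, b)]
        return out


# ---------------------------------------------------------------------------
# Column statistics and trimming
# ---------------------------------------------------------------------------

def gap_fraction_profile(aln: Alignment) -> np.ndarray:
    """Fraction of rows carrying a gap, per column (values in [0, 1])."""
    arr = aln.to_array()
    return (arr == GAP).mean(axis=0)


def trim_by_gap_threshold(
    aln: Alignment, gt: float
) -> tuple[Alignment, list[int]]:
    """Drop columns whose non-gap fraction falls below ``gt``.

    Returns the trimmed alignment and the 0-based indices of retained columns.
    Ties (non-gap fraction exactly ``gt``) are retained.  Rows left with no
    residues are kept, with a warning, so that row correspondence survives for
    downstream pairwise matrices.
    """
    if not 0.0 <= gt <= 1.0:
        raise DataValidationError(f"gap threshold {gt} outside [0, 1]")
    nongap = 1.0 - gap_fraction_profile(aln)
    retained = [j for j in range(aln.length) if nongap[j] >= gt]
    trimmed = aln.take_columns(retained)
    empty = [r.id for r in trimmed.rows if not r.ungapped()]
    if empty:
        logger.warning(
            "trim gt=%.3g left %d all-gap row(s): %s", gt, len(empty), empty
        )
    return trimmed, retained


def sweep_trim(aln: Alignment, thresholds: TypingSequence[float]) -> pd.DataFrame:
    """Trim at each threshold; tabulate retained column counts and fractions."""
    if len(thresholds) == 0:
        raise DataValidationError("threshold list must be non-empty")
    records = []
    for gt in thresholds:
        _, cols = trim_by_gap_threshold(aln, gt)
        records.append(
            {
                "gap_threshold": gt,
                "columns_retained": len(cols),
                "fraction_retained": len(cols) / aln.length if aln.length else 0.0,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Windowed similarity (Plotcon-style profile)
# ---------------------------------------------------------------------------

@dataclass
class ConservationTrack:
    """Windowed mean pairwise substitution score along an alignment."""

    values: np.ndarray
    window: int
    positions: np.ndarray  # 0-based columns of the window centres

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise DataValidationError(f"window {self.window} must be odd and >= 1")
        if len(self.values) != len(self.positions):
            raise DataValidationError("track values and positions disagree in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column_1based": self.positions + 1, "similarity": self.values}
        )


def windowed_similarity(
    aln: Alignment, matrix: SubstitutionMatrix | None = None, window: int = 11
) -> ConservationTrack:
    """Sliding-window mean pairwise similarity under a substitution matrix.

    Per column, the score is the mean over all unordered row pairs of the
    matrix score for the two residues; pairs where either residue is a gap or
    ``X`` contribute 0 and stay in the denominator.  The track value at a
    window centre is the mean column score across the window; centres run from
    ``(window-1)//2`` to ``length-1-(window-1)//2``.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.load("BLOSUM62")
    if window % 2 == 0 or window < 1:
        raise DataValidationError(f"window {window} must be odd and >= 1")
    if window > aln.length:
        raise DataValidationError(
            f"window {window} exceeds alignment length {aln.length}"
        )
    arr = aln.to_array()
    idx = np.full(arr.shape, -1, dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        idx[arr == a] = i
    lookup = matrix.as_lookup(AMINO_ACIDS)
    n = aln.n_rows
    pairs = [(i, k) for i in range(n) for k in range(i + 1, n)]
    col_scores = np.zeros(aln.length)
    for i, k in pairs:
        valid = (idx[i] >= 0) & (idx[k] >= 0)
        s = np.where(valid, lookup[idx[i], idx[k]], 0.0)
        col_scores += s
    col_scores /= len(pairs)
    kernel = np.ones(window) / window
    values = np.convolve(col_scores, kernel, mode="valid")
    half = (window - 1) // 2
    centers = np.arange(half, aln.length - half)
    return ConservationTrack(values=values, window=window, positions=centers)


# ---------------------------------------------------------------------------
# Reference-anchored positions
# ---------------------------------------------------------------------------

def map_reference_positions(
    aln: Alignment, ref_id: str, positions: TypingSequence[int]
) -> list[int]:
    """Map 1-based ungapped residue positions of a reference row to columns.

    Column ``j`` is returned for position ``p`` iff the reference row's p-th
    non-gap residue sits in column ``j``; output order follows input order.
    """
    ref = aln.row(ref_id)
    residue_to_column = [
        j for j, ch in enumerate(ref.residues) if ch != GAP
    ]
    n = len(residue_to_column)
    bad = [p for p in positions if not 1 <= p <= n]
    if bad:
        raise DataValidationError(
            f"positions out of range for {ref_id!r} (ungapped length {n}): {bad}"
        )
    return [residue_to_column[p - 1] for p in positions]
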
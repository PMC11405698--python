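"""Percent-identity matrices over specificity-determining residues.

A small set of alignment positions in the PDZ-domain ligand-binding groove
(β2/β3 strands and α2 helix; 17 residues in the reference analysis) predicts
shared C-terminal ligand specificity when pairwise identity over those
positions is high.  This module computes symmetric percent-identity matrices
over an arbitrary column subset or over the whole domain, and classifies
sequence pairs as shared / divergent specificity with inclusive thresholds
(defaults: 70% over the specificity subset, 50% over the full domain).

Positions where either residue is a gap or ``X`` are excluded from both the
numerator and the denominator; pairs with at most half the subset's
positions comparable carry a low-coverage flag, and a pair with no comparable
positions has an undefined (NaN) identity rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd

from .alignment import Alignment, GAP, UNKNOWN, map_reference_positions
from .errors import DataValidationError

SUBSET_IDENTITY_THRESHOLD = 70.0  # % over the specificity-residue subset
FULL_IDENTITY_THRESHOLD = 50.0    # % over the entire domain


@dataclass(frozen=True)
class SpecificityPositionSet:
    """Reference-anchored 1-based residue positions (e.g. the 17-residue set)."""

    label: str
    ref_id: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(self.positions)
        if not pos:
            raise DataValidationError("position set must be non-empty")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataValidationError(
                "positions must be strictly increasing and unique"
            )
        object.__setattr__(self, "positions", pos)

    def to_columns(self, aln: Alignment) -> list[int]:
        return map_reference_positions(aln, self.ref_id, list(self.positions))


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent identity with per-pair coverage counts."""

    values: pd.DataFrame    # % identity, NaN where undefined
    coverage: pd.DataFrame  # number of gap-free compared positions
    n_positions: int

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def identity(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def low_coverage(self, a: str, b: str) -> bool:
        # flagged when at most half the subset's positions were comparable
        return bool(2 * self.coverage.loc[a, b] <= self.n_positions)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class SpecificityCall:
    """Shared-specificity classification for one sequence pair."""

    pair: tuple[str, str]
    subset_identity: float
    full_identity: float
    subset_shared: bool | None
    full_shared: bool | None
    low_coverage: bool


def _pairwise_identity(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (% identity, coverage) matrices for a (n, m) residue array."""
    comparable = (arr != GAP) & (arr != UNKNOWN)
    n = arr.shape[0]
    ident = np.full((n, n), np.nan)
    cov = np.zeros((n, n), dtype=int)
    for i in range(n):
        for k in range(i, n):
            both = comparable[i] & comparable[k]
            c = int(both.sum())
            cov[i, k] = cov[k, i] = c
            if c > 0:
                matches = int((arr[i][both] == arr[k][both]).sum())
                ident[i, k] = ident[k, i] = 100.0 * matches / c
    return ident, cov


def subset_identity_matrix(
    aln: Alignment, columns: TypingSequence[int]
) -> IdentityMatrix:
    """Percent identity over a column subset (NaN when nothing is comparable)."""
    if len(columns) == 0:
        raise DataValidationError("column subset must be non-empty")
    sub = aln.take_columns(list(columns))
    ident, cov = _pairwise_identity(sub.to_array())
    labels = aln.ids
    return IdentityMatrix(
        values=pd.DataFrame(ident, index=labels, columns=labels),
        coverage=pd.DataFrame(cov, index=labels, columns=labels),
        n_positions=len(columns),
    )


def full_identity_matrix(aln: Alignment) -> IdentityMatrix:
    """Percent identity over every alignment column."""
    return subset_identity_matrix(aln, list(range(aln.length)))


def classify_shared_specificity(
    subset: IdentityMatrix,
    full: IdentityMatrix,
    subset_threshold: float = SUBSET_IDENTITY_THRESHOLD,
    full_threshold: float = FULL_IDENTITY_THRESHOLD,
) -> list[SpecificityCall]:
    """One shared/divergent call per unordered pair (ties count as shared).

    A missing identity (no comparable positions) yields a ``None`` flag rather
    than a spurious "not shared".
    """
    if subset.labels != full.labels:
        raise DataValidationError(
            "subset and full identity matrices must share labels"
        )
    calls = []
    labels = subset.labels
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            si = subset.identity(a, b)
            fi = full.identity(a, b)
            calls.append(
                SpecificityCall(
                    pair=(a, b),
                    subset_identity=si,
                    full_identity=fi,
                    subset_shared=None if math.isnan(si) else si >= subset_threshold,
                    full_shared=None if math.isnan(fi) else fi >= full_threshold,
                    low_coverage=subset.low_coverage(a, b),
                )
            )
    return calls


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "a": c.pair[0],
                "b": c.pair[1],
                "subset_identity": c.subset_identity,
                "full_identity": c.full_identity,
                "subset_shared": c.subset_shared,
                "full_shared": c.full_shared,
                "low_coverage": c.low_coverage,
            }
            for c in calls
        ]
    )
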
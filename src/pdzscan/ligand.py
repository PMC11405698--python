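"""C-terminal PDZ-ligand extraction, classification and consensus motifs.

PDZ domains read the extreme C-terminus of their partners.  Positions are
labelled −(k−1)…0 with 0 the protein's final residue, so "W at −1" means the
second-last residue.  Classes recognised here:

* ``DDWC_like`` — the non-canonical Ca_V_2-channel ligand: tryptophan at −1
  and cysteine at 0 (covers DDWC, DHWC, SEWC, ETWC variants);
* ``type_I`` — the canonical X-[S/T]-X-Φ ligand: serine/threonine at −2 and a
  hydrophobic residue at 0 (e.g. CTAV);
* ``W_minus1_other`` — tryptophan at −1 without the terminal cysteine and not
  type I;
* ``other`` — everything else (e.g. the ctenophore SGDI terminus).

Precedence is DDWC_like > type_I > W_minus1_other > other, so a peptide such
as ETWC (which also has T at −2) groups with the W/C ligands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence as TypingSequence

import pandas as pd

from .alignment import GAP, Sequence
from .errors import DataValidationError

#: Default hydrophobe set Φ for the type-I position-0 residue.
DEFAULT_HYDROPHOBES = frozenset("VILMFWAC")


class LigandClass(str, Enum):
    DDWC_LIKE = "DDWC_like"
    TYPE_I = "type_I"
    W_MINUS1_OTHER = "W_minus1_other"
    OTHER = "other"


@dataclass(frozen=True)
class CTerminalPeptide:
    """The last ``k`` residues of a protein, position 0 = final residue."""

    source_id: str
    residues: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataValidationError(f"empty C-terminal peptide for {self.source_id!r}")
        if GAP in self.residues:
            raise DataValidationError(
                f"gap character in C-terminal peptide of {self.source_id!r}"
            )

    def at(self, position: int) -> str:
        """Residue at a 0/−1/−2… position; '' when the peptide is too short."""
        if position > 0:
            raise DataValidationError("C-terminal positions are <= 0")
        i = len(self.residues) - 1 + position
        return self.residues[i] if i >= 0 else ""


@dataclass(frozen=True)
class LigandCall:
    """Classification of one peptide with its full feature-flag vector."""

    peptide: CTerminalPeptide
    ligand_class: LigandClass
    w_at_minus1: bool
    c_at_0: bool
    st_at_minus2: bool
    hydrophobe_at_0: bool
    kr_at_minus1: bool
    truncated: bool


def extract_cterminus(seq: Sequence, k: int = 4) -> CTerminalPeptide:
    """Last ``min(k, length)`` residues of a sequence (gaps removed first)."""
    if k < 1:
        raise DataValidationError(f"k must be positive, got {k}")
    residues = seq.ungapped()
    if not residues:
        raise DataValidationError(f"sequence {seq.id!r} has no residues")
    return CTerminalPeptide(
        source_id=seq.id,
        residues=residues[-k:],
        truncated=len(residues) < k,
    )


def classify_ligand(
    p: CTerminalPeptide,
    hydrophobes: frozenset[str] | set[str] = DEFAULT_HYDROPHOBES,
) -> LigandCall:
    """Assign exactly one ligand class by the documented precedence.

    Peptides shorter than 4 residues cannot be fully classified and fall to
    ``other`` with the truncation flag set; feature flags are populated from
    whatever positions exist.
    """
    w1 = p.at(-1) == "W"
    c0 = p.at(0) == "C"
    st2 = p.at(-2) in ("S", "T")
    h0 = p.at(0) in hydrophobes
    kr1 = p.at(-1) in ("K", "R")
    short = len(p.residues) < 4
    if short:
        cls = LigandClass.OTHER
    elif w1 and c0:
        cls = LigandClass.DDWC_LIKE
    elif st2 and h0:
        cls = LigandClass.TYPE_I
    elif w1:
        cls = LigandClass.W_MINUS1_OTHER
    else:
        cls = LigandClass.OTHER
    return LigandCall(
        peptide=p,
        ligand_class=cls,
        w_at_minus1=w1,
        c_at_0=c0,
        st_at_minus2=st2,
        hydrophobe_at_0=h0,
        kr_at_minus1=kr1,
        truncated=short or p.truncated,
    )


@dataclass
class MotifConsensus:
    """Per-position residue frequencies over a right-aligned peptide set."""

    frequencies: pd.DataFrame     # index: residues, columns: positions −(k−1)…0
    majority: str                 # one letter per position, ties alphabetical
    tie_positions: list[int]      # positions where the majority was a tie
    invariant_positions: list[int]  # positions with a single observed residue


def consensus_motif(
    peptides: TypingSequence[CTerminalPeptide], k: int = 4
) -> MotifConsensus:
    """Right-aligned per-position frequency table and majority consensus.

    Shorter peptides contribute only to the positions they cover; ties in the
    majority call break alphabetically and are flagged.
    """
    if k < 1:
        raise DataValidationError(f"k must be positive, got {k}")
    if not peptides:
        raise DataValidationError("need at least one peptide")
    positions = list(range(-(k - 1), 1))
    counts = {pos: Counter() for pos in positions}
    for p in peptides:
        for pos in positions:
            r = p.at(pos)
            if r:
                counts[pos][r] += 1
    freq = {}
    majority = []
    ties, invariant = [], []
    for pos in positions:
        c = counts[pos]
        total = sum(c.values())
        freq[pos] = {r: n / total for r, n in c.items()} if total else {}
        if not total:
            majority.append("x")
            continue
        best = max(c.values())
        winners = sorted(r for r, n in c.items() if n == best)
        majority.append(winners[0])
        if len(winners) > 1:
            ties.append(pos)
        if len(c) == 1:
            invariant.append(pos)
    residues = sorted({r for pos in positions for r in freq[pos]})
    table = pd.DataFrame(
        {pos: [freq[pos].get(r, 0.0) for r in residues] for pos in positions},
        index=residues,
    )
    return MotifConsensus(
        frequencies=table,
        majority="".join(majority),
        tie_positions=ties,
        invariant_positions=invariant,
    )


def motif_presence_table(
    seqs: Iterable[Sequence],
    target_class: LigandClass | str = LigandClass.DDWC_LIKE,
    k: int = 4,
    hydrophobes: frozenset[str] | set[str] = DEFAULT_HYDROPHOBES,
) -> pd.DataFrame:
    """Classify each sequence's C-terminus; flag membership in a target class.

    Extraction errors are recorded per row (class ``NA``) without aborting the
    rest of the table.
    """
    target = LigandClass(target_class)
    rows = []
    for s in seqs:
        try:
            call = classify_ligand(extract_cterminus(s, k), hydrophobes)
        except DataValidationError as exc:
            rows.append(
                {
                    "source_id": s.id,
                    "peptide": None,
                    "ligand_class": None,
                    "present": None,
                    "error": str(exc),
                }
            )
            continue
        rows.append(
            {
                "source_id": s.id,
                "peptide": call.peptide.residues,
                "ligand_class": call.ligand_class.value,
                "present": call.ligand_class == target,
                "error": None,
            }
        )
    return pd.DataFrame(
        rows, columns=["source_id", "peptide", "ligand_class", "present", "error"]
    )


def class_counts(table: pd.DataFrame) -> pd.Series:
    """Summary counts per ligand class from a presence table."""
    return table["ligand_class"].value_counts(dropna=True)
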
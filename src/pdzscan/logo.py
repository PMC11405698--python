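"""Position frequency matrices, information content and ligand signatures.

Input is a fixed-register C-terminal peptide library readout (the selected
pool of a bacterial 2-hybrid screen): every peptide has the same length L
(default 6) and a non-negative weight (read count).  Positions are labelled
−(L−1)…0, position 0 being the residue that would sit at a partner protein's
extreme C-terminus.

From the weighted counts the module derives a position frequency matrix (with
a small pseudocount), a per-position information-content track against a
uniform 20-residue background, IC_p = log2(20) − H_p, and a compact signature
string: informative positions (IC above a threshold) render their frequent
residues ('/'-joined, descending frequency), uninformative positions render
'x', and leading all-'x' positions are trimmed — e.g. "GxWV" or "WV".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS
from .errors import DataValidationError

MAX_IC_BITS = math.log2(20)
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_IC_THRESHOLD = 1.0    # bits
DEFAULT_FREQ_THRESHOLD = 0.2


@dataclass
class PeptideCountTable:
    """Weighted peptides of one fixed length L (positions −(L−1)…0)."""

    length: int
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DataValidationError("peptide length must be >= 1")
        clean: dict[str, float] = {}
        for pep, w in self.entries.items():
            pep = pep.upper()
            if len(pep) != self.length:
                raise DataValidationError(
                    f"peptide {pep!r} has length {len(pep)}, expected {self.length}"
                )
            if set(pep) - set(AMINO_ACIDS):
                raise DataValidationError(f"non-standard residue in {pep!r}")
            if w < 0:
                raise DataValidationError(f"negative weight for {pep!r}")
            clean[pep] = clean.get(pep, 0.0) + float(w)
        if sum(clean.values()) <= 0:
            raise DataValidationError("total peptide weight must be positive")
        self.entries = clean

    @property
    def positions(self) -> list[int]:
        return list(range(-(self.length - 1), 1))

    @property
    def total_weight(self) -> float:
        return sum(self.entries.values())

    @classmethod
    def from_tsv(cls, source) -> "PeptideCountTable":
        df = pd.read_csv(source, sep="\t")
        if not {"peptide", "weight"} <= set(df.columns):
            raise DataValidationError(
                "peptide count TSV needs 'peptide' and 'weight' columns"
            )
        if df.empty:
            raise DataValidationError("empty peptide count table")
        length = len(str(df["peptide"].iloc[0]))
        return cls(
            length=length,
            entries={str(p): float(w) for p, w in zip(df["peptide"], df["weight"])},
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"peptide": list(self.entries), "weight": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PositionFrequencyMatrix:
    """L columns of 20-residue frequencies; each column sums to 1."""

    frequencies: pd.DataFrame  # index: AMINO_ACIDS, columns: positions −(L−1)…0
    pseudocount: float

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DataValidationError("PFM columns must each sum to 1")
        if (self.frequencies.values < 0).any():
            raise DataValidationError("PFM frequencies must be non-negative")

    @property
    def positions(self) -> list[int]:
        return list(self.frequencies.columns)


@dataclass
class LogoTrack:
    """Per-position information content in bits (uniform background)."""

    bits: pd.Series  # index: positions

    def __post_init__(self) -> None:
        if ((self.bits < -1e-9) | (self.bits > MAX_IC_BITS + 1e-9)).any():
            raise DataValidationError("IC values must lie in [0, log2 20]")


@dataclass(frozen=True)
class LigandSignature:
    """Compact rendering like ``GxWV`` or ``E/DWL`` (left = most upstream)."""

    tokens: tuple[str, ...]     # one token per rendered position, e.g. ("G","x","W","V")
    positions: tuple[int, ...]  # the positions the tokens cover

    def __str__(self) -> str:
        return "".join(self.tokens)


def build_pfm(
    t: PeptideCountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> PositionFrequencyMatrix:
    """Weighted per-position residue frequencies with additive pseudocount.

    frequency(p, r) = (weighted count of r at p + pseudocount)
                      / (total weight + 20 * pseudocount)
    """
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be >= 0")
    positions = t.positions
    counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=positions)
    for pep, w in t.entries.items():
        for pos, res in zip(positions, pep):
            counts.loc[res, pos] += w
    freq = (counts + pseudocount) / (t.total_weight + 20 * pseudocount)
    return PositionFrequencyMatrix(frequencies=freq, pseudocount=pseudocount)


def information_content(pfm: PositionFrequencyMatrix) -> LogoTrack:
    """IC_p = log2(20) − H_p with H_p the Shannon entropy (0·log 0 = 0)."""
    f = pfm.frequencies.values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=0)
    bits = np.clip(MAX_IC_BITS - entropy, 0.0, MAX_IC_BITS)
    return LogoTrack(bits=pd.Series(bits, index=pfm.positions))


def signature(
    pfm: PositionFrequencyMatrix,
    track: LogoTrack | None = None,
    ic_threshold: float = DEFAULT_IC_THRESHOLD,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> LigandSignature:
    """Render informative positions; trim leading uninformative ones.

    Positions with IC below ``ic_threshold`` become 'x'; the rest list their
    residues with frequency >= ``freq_threshold``, '/'-joined in descending
    frequency (ties alphabetical).
    """
    if ic_threshold < 0 or freq_threshold < 0:
        raise DataValidationError("thresholds must be >= 0")
    if track is None:
        track = information_content(pfm)
    tokens: list[str] = []
    for pos in pfm.positions:
        if track.bits[pos] < ic_threshold:
            tokens.append("x")
            continue
        col = pfm.frequencies[pos]
        chosen = col[col >= freq_threshold]
        chosen = chosen.sort_values(ascending=False, kind="stable")
        order = sorted(chosen.index, key=lambda r: (-chosen[r], r))
        tokens.append("/".join(order) if order else "x")
    positions = pfm.positions
    start = 0
    while start < len(tokens) and tokens[start] == "x":
        start += 1
    return LigandSignature(
        tokens=tuple(tokens[start:]), positions=tuple(positions[start:])
    )


def compare_signatures(a: LigandSignature, b: LigandSignature) -> pd.DataFrame:
    """Right-aligned positionwise agreement (symmetric).

    Two tokens agree when they share at least one residue, or are both 'x'.
    Positions covered by only one signature are reported with agreement False.
    """
    positions = sorted(set(a.positions) | set(b.positions))
    tok_a = dict(zip(a.positions, a.tokens))
    tok_b = dict(zip(b.positions, b.tokens))
    rows = []
    for pos in positions:
        ta, tb = tok_a.get(pos), tok_b.get(pos)
        if ta is None or tb is None:
            agree = False
        elif ta == "x" or tb == "x":
            agree = ta == tb
        else:
            agree = bool(set(ta.split("/")) & set(tb.split("/")))
        rows.append({"position": pos, "a": ta, "b": tb, "agree": agree})
    return pd.DataFrame(rows)


def plot_logo(pfm: PositionFrequencyMatrix, ax=None):
    """Minimal information-content logo: letters stacked to their bit share."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(pfm.positions), 3))
    track = information_content(pfm)
    for x, pos in enumerate(pfm.positions):
        col = pfm.frequencies[pos].sort_values()
        y = 0.0
        for res, f in col.items():
            h = f * track.bits[pos]
            if h < 0.01:
                continue
            ax.text(
                x, y + h / 2, res, ha="center", va="center",
                fontsize=8 + 14 * h / MAX_IC_BITS, family="monospace",
            )
            y += h
    ax.set_xticks(range(len(pfm.positions)))
    ax.set_xticklabels(pfm.positions)
    ax.set_ylim(0, MAX_IC_BITS)
    ax.set_xlim(-0.5, len(pfm.positions) - 0.5)
    ax.set_xlabel("position (0 = C-terminus)")
    ax.set_ylabel("bits")
    return ax
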
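"""Two-hybrid screen hit tables and colony-weighted motif statistics.

A screen hit table records, per prey, the C-terminal decapeptide recovered
from the library and the number of colonies it produced; annotation columns
(homologue name, species, accession, E-value, …) are carried through verbatim.
Statistics default to colony weighting — each colony counts one unit — because
screen totals are colony sums, not unique-prey counts; unweighted variants
support unique-prey statements.

The two packaged example tables (``table1A.tsv`` transcribed from a screen
with a tandem PDZ-1/PDZ-2/P1BM bait, ``table1B.tsv`` from a PDZ-1-only bait,
both against a *T. adhaerens* prey library) ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import DataValidationError

#: Sentinel used when a prey could not be mapped to a gene model.
MISSING_PREY = "Not found"

_REQUIRED_COLUMNS = ("cterm", "colonies")


@dataclass(frozen=True)
class HitRecord:
    prey_id: str
    cterm: str
    colonies: int
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cterm or "-" in self.cterm:
            raise DataValidationError(
                f"invalid C-terminal peptide {self.cterm!r} for prey {self.prey_id!r}"
            )
        if self.colonies < 1:
            raise DataValidationError(
                f"colony count must be >= 1 for prey {self.prey_id!r}"
            )


@dataclass
class HitTable:
    screen_label: str
    records: list[HitRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise DataValidationError("hit table must contain at least one record")
        keys = [(r.prey_id, r.cterm) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DataValidationError(f"duplicate (prey_id, cterm) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def drop(self, prey_id: str, cterm: str) -> "HitTable":
        """A copy without one record (e.g. excluding the top-ranked prey)."""
        kept = [
            r for r in self.records if (r.prey_id, r.cterm) != (prey_id, cterm)
        ]
        return HitTable(self.screen_label, kept)


def load_hit_table(source, screen_label: str = "") -> HitTable:
    """Read a TSV with at least ``cterm`` and ``colonies`` columns.

    Extra columns are preserved verbatim as annotation; a missing/absent
    ``prey_id`` becomes the explicit :data:`MISSING_PREY` sentinel.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"hit table missing required columns: {missing}")
    records = []
    extra = [c for c in df.columns if c not in ("prey_id", *_REQUIRED_COLUMNS)]
    for i, row in df.iterrows():
        raw = row["colonies"]
        try:
            colonies = int(raw)
        except (TypeError, ValueError):
            raise DataValidationError(
                f"row {i + 1}: colony count {raw!r} is not an integer"
            ) from None
        if colonies < 1:
            raise DataValidationError(f"row {i + 1}: colony count {colonies} < 1")
        prey = row.get("prey_id")
        prey = MISSING_PREY if pd.isna(prey) or not str(prey).strip() else str(prey)
        records.append(
            HitRecord(
                prey_id=prey,
                cterm=str(row["cterm"]).strip().upper(),
                colonies=colonies,
                annotation={c: row[c] for c in extra},
            )
        )
    return HitTable(screen_label=screen_label, records=records)


def packaged_table(which: str) -> HitTable:
    """Load a packaged example table: ``'A'`` (tandem bait) or ``'B'`` (PDZ-1)."""
    name = {"A": "table1A.tsv", "B": "table1B.tsv"}.get(which.upper())
    if name is None:
        raise DataValidationError(f"unknown packaged table {which!r}")
    ref = resources.files("pdzscan.data").joinpath(name)
    with ref.open() as fh:
        return load_hit_table(fh, screen_label=f"screen_{which.upper()}")


def _weight(r: HitRecord, weighted: bool) -> int:
    return r.colonies if weighted else 1


def total_hits(t: HitTable, weighted: bool = True) -> int:
    """Colony sum (weighted) or record count (unweighted)."""
    return sum(_weight(r, weighted) for r in t.records)


def count_suffix(t: HitTable, suffix: str, weighted: bool = True) -> int:
    """Weight of records whose C-terminus ends with ``suffix`` (case-insensitive)."""
    if not suffix:
        raise DataValidationError("suffix must be non-empty")
    s = suffix.upper()
    return sum(
        _weight(r, weighted) for r in t.records if r.cterm.upper().endswith(s)
    )


def count_terminal_residue(
    t: HitTable,
    residues: set[str] | frozenset[str] | str,
    weighted: bool = True,
    invert: bool = False,
) -> int:
    """Weight of records whose final residue is in (or out of) a residue set."""
    rset = {r.upper() for r in residues}
    if not rset:
        raise DataValidationError("residue set must be non-empty")
    return sum(
        _weight(r, weighted)
        for r in t.records
        if (r.cterm[-1].upper() in rset) != invert
    )


def rank_prey(t: HitTable) -> list[HitRecord]:
    """Records sorted by colonies descending, ties alphabetical by cterm."""
    return sorted(t.records, key=lambda r: (-r.colonies, r.cterm))


def terminal_distribution(t: HitTable, weighted: bool = True) -> pd.Series:
    """Counts over final residues; sums to :func:`total_hits`."""
    counts: dict[str, int] = {}
    for r in t.records:
        res = r.cterm[-1].upper()
        counts[res] = counts.get(res, 0) + _weight(r, weighted)
    return pd.Series(counts).sort_values(ascending=False)
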
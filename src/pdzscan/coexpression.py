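"""Gene co-expression across metacells: binary calls, Venn partitions, rates.

A metacell aggregates transcriptionally similar single cells into one
expression unit; the same machinery applies to per-cell or per-image counts.
Expression calls are binary — a unit "expresses" a gene when its value is
strictly above a threshold (default 0) — and all downstream statistics
(counts, three-set Venn partitions, conditional co-expression percentages,
positive-control calibration) operate on these calls, optionally restricted
to a cell-type annotation (e.g. neurons only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError


@dataclass
class MetacellExpressionMatrix:
    """Genes × metacells non-negative expression with optional cell types."""

    values: pd.DataFrame                 # index: genes, columns: metacells
    celltypes: pd.Series | None = None   # index: metacells

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DataValidationError("gene and metacell labels must be unique")
        if (self.values.values < 0).any():
            raise DataValidationError("expression values must be non-negative")
        if self.celltypes is not None:
            missing = self.values.columns.difference(self.celltypes.index)
            if len(missing):
                raise DataValidationError(
                    f"metacells without cell-type annotation: {list(missing)[:5]}"
                )
            self.celltypes = self.celltypes.reindex(self.values.columns)

    @classmethod
    def from_tsv(cls, matrix_path, annotation_path=None) -> "MetacellExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        celltypes = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
            celltypes = ann.iloc[:, 0]
        return cls(values=values, celltypes=celltypes)


@dataclass
class ExpressionCallMatrix:
    """Binary expressed/not-expressed calls with the threshold that made them."""

    calls: pd.DataFrame
    threshold: float
    celltypes: pd.Series | None = None

    def universe(self, celltype: str | None = None) -> pd.Index:
        """Metacell labels, optionally restricted to one cell type."""
        if celltype is None:
            return self.calls.columns
        if self.celltypes is None:
            raise DataValidationError("no cell-type annotation available")
        mask = self.celltypes == celltype
        if not mask.any() and celltype not in set(self.celltypes):
            raise DataValidationError(f"unknown cell type {celltype!r}")
        return self.calls.columns[mask.values]

    def gene_calls(self, gene: str, celltype: str | None = None) -> pd.Series:
        if gene not in self.calls.index:
            raise DataValidationError(f"unknown gene {gene!r}")
        return self.calls.loc[gene, self.universe(celltype)]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint three-set region counts; regions + none = universe size."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    none: int

    @property
    def universe(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab_only + self.ac_only + self.bc_only
            + self.abc + self.none
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "A_only": self.a_only, "B_only": self.b_only, "C_only": self.c_only,
            "AB_only": self.ab_only, "AC_only": self.ac_only,
            "BC_only": self.bc_only, "ABC": self.abc, "none": self.none,
        }


def binarize(m: MetacellExpressionMatrix, threshold: float = 0.0) -> ExpressionCallMatrix:
    """Call a gene expressed in a unit when value > threshold (strictly)."""
    if threshold < 0:
        raise DataValidationError("threshold must be >= 0")
    calls = (m.values > threshold).astype(int)
    return ExpressionCallMatrix(
        calls=calls, threshold=threshold, celltypes=m.celltypes
    )


def count_expressing(
    c: ExpressionCallMatrix, gene: str, celltype: str | None = None
) -> tuple[int, int]:
    """(number of filtered units with call 1, filtered-universe size)."""
    calls = c.gene_calls(gene, celltype)
    return int(calls.sum()), int(len(calls))


def venn3(
    c: ExpressionCallMatrix,
    a: str,
    b: str,
    d: str,
    celltype: str | None = None,
) -> VennPartition:
    """Counts of the 7 disjoint regions of three genes' call sets, plus none."""
    if len({a, b, d}) != 3:
        raise DataValidationError("venn3 needs three distinct gene labels")
    ca = c.gene_calls(a, celltype).values.astype(bool)
    cb = c.gene_calls(b, celltype).values.astype(bool)
    cd = c.gene_calls(d, celltype).values.astype(bool)
    return VennPartition(
        a_only=int((ca & ~cb & ~cd).sum()),
        b_only=int((~ca & cb & ~cd).sum()),
        c_only=int((~ca & ~cb & cd).sum()),
        ab_only=int((ca & cb & ~cd).sum()),
        ac_only=int((ca & ~cb & cd).sum()),
        bc_only=int((~ca & cb & cd).sum()),
        abc=int((ca & cb & cd).sum()),
        none=int((~ca & ~cb & ~cd).sum()),
    )


def pct_coexpression(
    c: ExpressionCallMatrix,
    ref: str,
    other: str,
    celltype: str | None = None,
) -> float:
    """Of the units expressing ``ref``, the percent also expressing ``other``."""
    cref = c.gene_calls(ref, celltype).values.astype(bool)
    cother = c.gene_calls(other, celltype).values.astype(bool)
    n_ref = int(cref.sum())
    if n_ref == 0:
        raise DataValidationError(
            f"gene {ref!r} is expressed in no filtered unit; percentage undefined"
        )
    return 100.0 * int((cref & cother).sum()) / n_ref


def calibration_compare(
    c: ExpressionCallMatrix,
    ref: str,
    candidates: list[str],
    positive_control: str,
    celltype: str | None = None,
    comparable_factor: float = 1.5,
) -> pd.DataFrame:
    """Candidate co-expression rates against a positive-control gene.

    The control is a gene biologically required to co-occur with ``ref``
    (e.g. an obligate channel subunit); a candidate whose rate falls within
    ``comparable_factor`` of the control's is flagged comparable, calibrating
    how much co-expression the data can show at best.
    """
    control_pct = pct_coexpression(c, ref, positive_control, celltype)
    rows = []
    for gene in [*candidates, positive_control]:
        pct = pct_coexpression(c, ref, gene, celltype)
        ratio = pct / control_pct if control_pct > 0 else np.nan
        rows.append(
            {
                "gene": gene,
                "pct_coexpression": pct,
                "ratio_to_control": ratio,
                "comparable_to_control": bool(
                    ratio >= 1.0 / comparable_factor and ratio <= comparable_factor
                ),
                "is_control": gene == positive_control,
            }
        )
    return pd.DataFrame(rows)
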
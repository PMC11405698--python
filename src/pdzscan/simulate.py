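"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its parameters and seed (bit-identical
repeats) and returns ``(data, GroundTruth)``, where the ground truth records
every planted parameter needed to compute the expected value of the
downstream estimate — identities at designated alignment columns, C-terminal
ligand class labels, planted motif positions, suffix plants in hit tables,
conditional co-expression rates, and assay effect ratios.

The alignment generator uses a star model per column: each row keeps the
column's consensus residue with probability p, otherwise draws uniformly from
the other 19 residues, so the pairwise expected identity is
``q = p^2 + (1-p)^2/19``; p is solved from the requested q as
``p = (1 + sqrt(380 q - 19)) / 20``.  Identities below the random-matching
floor (380q < 19) are infeasible and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, Alignment, Sequence
from .coexpression import MetacellExpressionMatrix
from .errors import DataValidationError
from .ligand import DEFAULT_HYDROPHOBES, LigandClass
from .logo import PeptideCountTable
from .screen import HitRecord, HitTable
from .assay import AssayWell

_AA = np.array(list(AMINO_ACIDS))
_NON_HYDROPHOBES = sorted(set(AMINO_ACIDS) - DEFAULT_HYDROPHOBES)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of one generator call."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Alignment families with controlled identity
# ---------------------------------------------------------------------------

def _keep_probability(q: float) -> float:
    """Solve q = p^2 + (1-p)^2 / 19 for the consensus-keep probability p."""
    disc = 380.0 * q - 19.0
    if disc < 0:
        raise DataValidationError(
            f"pairwise identity {q} below the random-matching floor (0.05)"
        )
    p = (1.0 + math.sqrt(disc)) / 20.0
    if p > 1.0 + 1e-12:
        raise DataValidationError(f"pairwise identity {q} infeasible")
    return min(p, 1.0)


def gen_alignment_family(
    n_seqs: int = 8,
    length: int = 90,
    designated_columns: tuple[int, ...] = (),
    subset_identity: float = 0.75,
    background_identity: float = 0.4,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> tuple[Alignment, GroundTruth]:
    """A protein family with designed identity at designated columns.

    Pairwise expected identity is ``subset_identity`` at the designated
    columns and ``background_identity`` elsewhere; gaps are inserted at
    ``gap_rate`` only outside designated columns.
    """
    if n_seqs < 2 or length < 1:
        raise DataValidationError("need n_seqs >= 2 and length >= 1")
    if not 0.0 <= gap_rate <= 1.0:
        raise DataValidationError("gap_rate must lie in [0, 1]")
    designated = set(designated_columns)
    if designated and (min(designated) < 0 or max(designated) >= length):
        raise DataValidationError("designated columns out of range")
    p_sub = _keep_probability(subset_identity)
    p_bg = _keep_probability(background_identity)
    rng = _rng(seed)
    consensus = rng.choice(_AA, size=length)
    rows = []
    for i in range(n_seqs):
        chars = []
        for j in range(length):
            p = p_sub if j in designated else p_bg
            if rng.random() < p:
                ch = consensus[j]
            else:
                others = [a for a in AMINO_ACIDS if a != consensus[j]]
                ch = others[rng.integers(len(others))]
            if j not in designated and rng.random() < gap_rate:
                ch = "-"
            chars.append(ch)
        if all(c == "-" for c in chars):  # keep rows legal under heavy gapping
            chars[rng.integers(length)] = consensus[rng.integers(length)]
        rows.append(Sequence(f"seq{i}", "".join(chars)))
    gt = GroundTruth(
        generator="gen_alignment_family",
        seed=seed,
        params={
            "n_seqs": n_seqs,
            "length": length,
            "designated_columns": sorted(designated),
            "subset_identity": subset_identity,
            "background_identity": background_identity,
            "gap_rate": gap_rate,
            "keep_probability_subset": p_sub,
            "keep_probability_background": p_bg,
        },
    )
    return Alignment(rows), gt


# ---------------------------------------------------------------------------
# C-termini with planted ligand classes
# ---------------------------------------------------------------------------

def _plant_terminal_4mer(
    rng: np.random.Generator, cls: LigandClass, dual_feature: bool
) -> str:
    aa = AMINO_ACIDS
    st = "ST"
    hyd = sorted(DEFAULT_HYDROPHOBES)
    r = lambda pool: pool[rng.integers(len(pool))]
    if cls is LigandClass.DDWC_LIKE:
        m2 = r(st) if dual_feature else r([a for a in aa if a not in st])
        return r(aa) + m2 + "W" + "C"
    if cls is LigandClass.TYPE_I:
        m1 = r([a for a in aa if a != "W"])
        return r(aa) + r(st) + m1 + r(hyd)
    if cls is LigandClass.W_MINUS1_OTHER:
        p0 = r([a for a in _NON_HYDROPHOBES])  # excludes C (hydrophobe set)
        return r(aa) + r(aa) + "W" + p0
    # other: no W at -1, and not (S/T at -2 with hydrophobe at 0)
    m1 = r([a for a in aa if a != "W"])
    return r(aa) + r(aa) + m1 + r(_NON_HYDROPHOBES)


def gen_ctermini(
    class_mix: dict,
    n: int = 100,
    seed: int = 0,
    dual_feature: bool = False,
    body_length: tuple[int, int] = (16, 40),
) -> tuple[list[Sequence], GroundTruth]:
    """Protein sequences ending in unambiguous instances of planted classes.

    ``class_mix`` maps :class:`LigandClass` (or its value string) to a
    proportion; proportions must sum to 1.  ``dual_feature=True`` makes
    DDWC-like plants carry S/T at −2 as well (ETWC-style), exercising the
    classification precedence.
    """
    if n < 1:
        raise DataValidationError("n must be >= 1")
    classes = [LigandClass(k) for k in class_mix]
    probs = np.array([float(class_mix[k]) for k in class_mix], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise DataValidationError("class proportions must sum to 1")
    rng = _rng(seed)
    labels = rng.choice(len(classes), size=n, p=probs)
    seqs, planted = [], []
    for i, li in enumerate(labels):
        cls = classes[li]
        blen = int(rng.integers(body_length[0], body_length[1] + 1))
        body = "".join(rng.choice(_AA, size=blen))
        seqs.append(Sequence(f"ct{i}", body + _plant_terminal_4mer(rng, cls, dual_feature)))
        planted.append(cls.value)
    gt = GroundTruth(
        generator="gen_ctermini",
        seed=seed,
        params={
            "n": n,
            "class_mix": {LigandClass(k).value: float(v) for k, v in class_mix.items()},
            "dual_feature": dual_feature,
            "labels": planted,
        },
    )
    return seqs, gt


# ---------------------------------------------------------------------------
# Peptide libraries with planted position-specific enrichment
# ---------------------------------------------------------------------------

def gen_peptide_library(
    length: int = 6,
    planted: dict[int, str] | None = None,
    enrichment_factor: float = 10.0,
    n_distinct: int = 2000,
    total_weight: float = 5000,
    seed: int = 0,
) -> tuple[PeptideCountTable, GroundTruth]:
    """A selected-pool hexamer library over a uniform background.

    At each planted position the planted residue is drawn at
    ``enrichment_factor`` times its uniform background frequency
    (probability f/20, so f = 10 plants the residue in half the reads); the
    other 19 residues share the remainder equally, and all other positions
    are uniform.  Weights are multinomial over the distinct peptides.
    """
    planted = dict(planted or {})
    if not 1 <= enrichment_factor <= 20:
        raise DataValidationError(
            "enrichment_factor must lie in [1, 20] (20 x background = fixed residue)"
        )
    for pos, res in planted.items():
        if not -(length - 1) <= pos <= 0:
            raise DataValidationError(f"planted position {pos} outside register")
        if res not in AMINO_ACIDS:
            raise DataValidationError(f"invalid planted residue {res!r}")
    rng = _rng(seed)
    positions = list(range(-(length - 1), 1))
    col_probs = []
    for pos in positions:
        p = np.full(20, 1.0 / 20)
        if pos in planted:
            p_planted = enrichment_factor / 20.0
            p = np.full(20, (1.0 - p_planted) / 19.0)
            p[AMINO_ACIDS.index(planted[pos])] = p_planted
        col_probs.append(p)
    peptides = []
    for _ in range(n_distinct):
        peptides.append(
            "".join(_AA[rng.choice(20, p=p)] for p in col_probs)
        )
    weights = rng.multinomial(int(total_weight), np.ones(n_distinct) / n_distinct)
    entries: dict[str, float] = {}
    for pep, w in zip(peptides, weights):
        if w > 0:
            entries[pep] = entries.get(pep, 0.0) + float(w)
    table = PeptideCountTable(length=length, entries=entries)
    gt = GroundTruth(
        generator="gen_peptide_library",
        seed=seed,
        params={
            "length": length,
            "planted": {int(k): v for k, v in planted.items()},
            "enrichment_factor": enrichment_factor,
            "n_distinct": n_distinct,
            "total_weight": total_weight,
        },
    )
    return table, gt


# ---------------------------------------------------------------------------
# Two-hybrid hit tables
# ---------------------------------------------------------------------------

def gen_hit_table(
    n_prey: int = 12,
    colony_dist=None,
    terminal_v_fraction: float = 0.75,
    suffix_plants: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[HitTable, GroundTruth]:
    """A screen hit table with planted terminal composition and suffixes.

    ``colony_dist`` may be a sequence to sample colony counts from, a callable
    ``f(rng) -> int``, or None for 1 + Poisson(0.5).  ``suffix_plants`` maps a
    suffix to the number of prey forced to end with it; non-planted prey are
    re-drawn so they never match a planted suffix, keeping the planted weight
    sum exact.
    """
    if n_prey < 1:
        raise DataValidationError("n_prey must be >= 1")
    if not 0.0 <= terminal_v_fraction <= 1.0:
        raise DataValidationError("terminal_v_fraction must lie in [0, 1]")
    suffix_plants = dict(suffix_plants or {})
    n_planted = sum(suffix_plants.values())
    if n_planted > n_prey:
        raise DataValidationError("more planted suffixes than prey")
    rng = _rng(seed)

    def draw_colonies() -> int:
        if colony_dist is None:
            return 1 + int(rng.poisson(0.5))
        if callable(colony_dist):
            return int(colony_dist(rng))
        return int(colony_dist[rng.integers(len(colony_dist))])

    def random_cterm() -> str:
        pep = "".join(rng.choice(_AA, size=9))
        last = "V" if rng.random() < terminal_v_fraction else \
            _NON_V[rng.integers(len(_NON_V))]
        return pep + last

    records: list[HitRecord] = []
    plant_assignments: list[str | None] = []
    for suffix, count in suffix_plants.items():
        plant_assignments.extend([suffix] * count)
    plant_assignments.extend([None] * (n_prey - n_planted))
    planted_weights: dict[str, int] = {s: 0 for s in suffix_plants}
    for i, suffix in enumerate(plant_assignments):
        if suffix is not None:
            stem = "".join(rng.choice(_AA, size=10 - len(suffix)))
            cterm = stem + suffix.upper()
        else:
            cterm = random_cterm()
            while any(cterm.endswith(s.upper()) for s in suffix_plants):
                cterm = random_cterm()
        colonies = draw_colonies()
        if suffix is not None:
            planted_weights[suffix] += colonies
        records.append(
            HitRecord(prey_id=f"prey_{i:04d}", cterm=cterm, colonies=colonies)
        )
    table = HitTable(screen_label=f"synthetic_seed{seed}", records=records)
    gt = GroundTruth(
        generator="gen_hit_table",
        seed=seed,
        params={
            "n_prey": n_prey,
            "terminal_v_fraction": terminal_v_fraction,
            "suffix_plants": suffix_plants,
            "planted_suffix_weights": planted_weights,
            "total_colonies": sum(r.colonies for r in records),
        },
    )
    return table, gt


_NON_V = [a for a in AMINO_ACIDS if a != "V"]


# ---------------------------------------------------------------------------
# Metacell matrices with designed co-expression
# ---------------------------------------------------------------------------

def gen_metacell_matrix(
    n_metacells: int = 1000,
    prevalence: dict[str, float] | None = None,
    celltype_fractions: dict[str, float] | None = None,
    conditional: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> tuple[MetacellExpressionMatrix, GroundTruth]:
    """A genes × metacells matrix with designed conditional co-expression.

    ``prevalence`` maps gene → marginal expression probability (it defines the
    gene set).  ``conditional`` maps (ref, other) → P(other expressed | ref
    expressed); the other gene's ref-negative rate is solved so its marginal
    prevalence is preserved, and an unsatisfiable design raises.  Expression
    values of called entries are exponential with unit mean (only the binary
    call matters downstream).
    """
    prevalence = dict(prevalence or {})
    conditional = dict(conditional or {})
    if not prevalence:
        raise DataValidationError("prevalence must define at least one gene")
    for g, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise DataValidationError(f"prevalence for {g!r} outside [0, 1]")
    dependents = set()
    for (ref, other), c in conditional.items():
        if not 0.0 <= c <= 1.0:
            raise DataValidationError(
                f"conditional co-expression for ({ref},{other}) outside [0, 1]"
            )
        if ref not in prevalence or other not in prevalence:
            raise DataValidationError("conditional pair references unknown gene")
        if other in dependents:
            raise DataValidationError(
                f"gene {other!r} is the dependent of more than one pair"
            )
        dependents.add(other)
    rng = _rng(seed)
    celltype_fractions = dict(celltype_fractions or {"cell": 1.0})
    if abs(sum(celltype_fractions.values()) - 1.0) > 1e-9:
        raise DataValidationError("celltype fractions must sum to 1")
    types = list(celltype_fractions)
    assignments = rng.choice(
        types, size=n_metacells, p=[celltype_fractions[t] for t in types]
    )
    metacells = [f"mc{i}" for i in range(n_metacells)]
    calls: dict[str, np.ndarray] = {}
    for g in prevalence:
        if g not in dependents:
            calls[g] = rng.random(n_metacells) < prevalence[g]
    for (ref, other), c in conditional.items():
        p_ref, p_other = prevalence[ref], prevalence[other]
        if p_ref < 1.0:
            p0 = (p_other - c * p_ref) / (1.0 - p_ref)
        else:
            p0 = 0.0
        if not -1e-9 <= p0 <= 1.0 + 1e-9:
            raise DataValidationError(
                f"design for ({ref},{other}) cannot preserve marginal prevalence"
            )
        p0 = min(max(p0, 0.0), 1.0)
        u = rng.random(n_metacells)
        calls[other] = np.where(calls[ref], u < c, u < p0)
    genes = list(prevalence)
    values = np.zeros((len(genes), n_metacells))
    for gi, g in enumerate(genes):
        on = calls[g]
        values[gi, on] = rng.exponential(1.0, size=int(on.sum())) + 1e-6
    import pandas as pd

    matrix = MetacellExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=metacells),
        celltypes=pd.Series(assignments, index=metacells),
    )
    gt = GroundTruth(
        generator="gen_metacell_matrix",
        seed=seed,
        params={
            "n_metacells": n_metacells,
            "prevalence": prevalence,
            "celltype_fractions": celltype_fractions,
            "conditional": {f"{r}|{o}": c for (r, o), c in conditional.items()},
        },
    )
    return matrix, gt


# ---------------------------------------------------------------------------
# Reporter-assay wells
# ---------------------------------------------------------------------------

def gen_assay(
    conditions: dict[str, float],
    replicates: int = 6,
    noise_sd: float = 0.1,
    seed: int = 0,
    control_label: str = "control",
) -> tuple[list[AssayWell], GroundTruth]:
    """Assay wells with designed activity ratios relative to a control.

    Each well's true activity is ``ratio * 1000 * (1 + N(0, noise_sd))``
    (floored at 0), back-converted to plausible A420/OD600/t/V tuples.  The
    control condition is added with ratio 1 if absent.
    """
    if replicates < 2:
        raise DataValidationError("need at least 2 replicates")
    if noise_sd < 0:
        raise DataValidationError("noise_sd must be >= 0")
    conditions = dict(conditions)
    conditions.setdefault(control_label, 1.0)
    rng = _rng(seed)
    wells: list[AssayWell] = []
    base = 1000.0
    for cond, ratio in conditions.items():
        if ratio < 0:
            raise DataValidationError(f"ratio for {cond!r} must be >= 0")
        for rep in range(1, replicates + 1):
            activity = max(ratio * base * (1.0 + rng.normal(0.0, noise_sd)), 0.0)
            od600 = float(rng.uniform(0.4, 0.8))
            t_min, volume = 30.0, 0.1
            a420 = activity * t_min * volume * od600 / 1000.0
            wells.append(
                AssayWell(
                    condition=cond, replicate=rep, a420=a420,
                    od600=od600, t_min=t_min, volume_ml=volume,
                )
            )
    gt = GroundTruth(
        generator="gen_assay",
        seed=seed,
        params={
            "conditions": conditions,
            "replicates": replicates,
            "noise_sd": noise_sd,
            "control": control_label,
        },
    )
    return wells, gt
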
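"""Stage orchestration: config, dependency-ordered execution, run reports.

A pipeline run is described by a small config mapping (YAML or dict): a seed,
an output directory, the list of stages to run, and one parameter block per
stage.  Stages execute in a fixed order, each writing its outputs in its
module's formats and contributing a summary to the run report; a failing
stage is recorded with its error and the remaining stages still run.  The
full parameter echo goes into the report so every threshold choice is visible
next to the numbers it produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import alignment as aln_mod
from . import assay as assay_mod
from . import coexpression as coex_mod
from . import ligand as ligand_mod
from . import logo as logo_mod
from . import screen as screen_mod
from . import specificity as spec_mod
from .errors import DataValidationError, PdzScanError

logger = logging.getLogger("pdzscan")

STAGE_ORDER = (
    "trim", "sweep", "simplot", "specmatrix",
    "classify", "screen_stats", "logo", "coexpr", "assay",
)


@dataclass
class PipelineConfig:
    stages: list[str]
    outdir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise DataValidationError(f"unknown stages: {unknown}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return cls(
            stages=list(raw.get("stages", [])),
            outdir=Path(raw.get("outdir", "pdzscan_out")),
            seed=int(raw.get("seed", 0)),
            params={k: v for k, v in raw.items()
                    if k not in ("stages", "outdir", "seed")},
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages in dependency order; return the run report."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_echo": {"stages": config.stages, **config.params},
        "stages": {},
        "warnings": [],
    }
    handler = _WarningCollector(report["warnings"])
    logger.addHandler(handler)
    try:
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            runner = _STAGE_RUNNERS[stage]
            try:
                report["stages"][stage] = runner(
                    config.params.get(stage, {}), config.outdir, config.seed
                )
            except PdzScanError as exc:
                logger.error("stage %s failed: %s", stage, exc)
                report["stages"][stage] = {"error": str(exc)}
    finally:
        logger.removeHandler(handler)
    with open(config.outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


class _WarningCollector(logging.Handler):
    def __init__(self, sink: list):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record.getMessage())


def _load_alignment(params: dict) -> aln_mod.Alignment:
    if "alignment" not in params:
        raise DataValidationError("stage needs an 'alignment' FASTA path")
    return aln_mod.read_alignment(params["alignment"])


def _run_trim(params: dict, outdir: Path, seed: int) -> dict:
    aln = _load_alignment(params)
    gt = float(params.get("gap_threshold", 0.9))
    trimmed, cols = aln_mod.trim_by_gap_threshold(aln, gt)
    aln_mod.write_fasta(trimmed, outdir / "trimmed.fasta")
    return {
        "gap_threshold": gt,
        "columns_retained": len(cols),
        "columns_total": aln.length,
        "output": "trimmed.fasta",
    }


def _run_sweep(params: dict, outdir: Path, seed: int) -> dict:
    aln = _load_alignment(params)
    thresholds = params.get("thresholds", [0.6, 0.7, 0.8, 0.9, 0.95])
    table = aln_mod.sweep_trim(aln, thresholds)
    table.to_csv(outdir / "trim_sweep.tsv", sep="\t", index=False)
    return {"thresholds": list(thresholds),
            "columns_retained": table["columns_retained"].tolist(),
            "output": "trim_sweep.tsv"}


def _run_simplot(params: dict, outdir: Path, seed: int) -> dict:
    aln = _load_alignment(params)
    window = int(params.get("window", 11))
    name = params.get("matrix", "BLOSUM62")
    matrix = (aln_mod.SubstitutionMatrix.from_file(name)
              if Path(str(name)).is_file()
              else aln_mod.SubstitutionMatrix.load(str(name)))
    track = aln_mod.windowed_similarity(aln, matrix, window)
    track.to_frame().to_csv(outdir / "similarity.tsv", sep="\t", index=False)
    return {"window": window, "matrix": matrix.name,
            "n_centers": len(track.values),
            "mean_similarity": float(track.values.mean()),
            "output": "similarity.tsv"}


def _run_specmatrix(params: dict, outdir: Path, seed: int) -> dict:
    aln = _load_alignment(params)
    pos_cfg = params.get("positions")
    if not pos_cfg:
        raise DataValidationError("specmatrix needs a 'positions' config entry")
    pset = spec_mod.SpecificityPositionSet(
        label=pos_cfg.get("label", "specificity set"),
        ref_id=pos_cfg["ref_id"],
        positions=tuple(pos_cfg["positions"]),
    )
    columns = pset.to_columns(aln)
    subset = spec_mod.subset_identity_matrix(aln, columns)
    full = spec_mod.full_identity_matrix(aln)
    calls = spec_mod.classify_shared_specificity(
        subset, full,
        subset_threshold=float(params.get("subset_threshold", 70.0)),
        full_threshold=float(params.get("full_threshold", 50.0)),
    )
    subset.to_tsv(outdir / "subset_identity.tsv")
    full.to_tsv(outdir / "full_identity.tsv")
    frame = spec_mod.calls_to_frame(calls)
    frame.to_csv(outdir / "specificity_calls.tsv", sep="\t", index=False)
    return {
        "position_set": pset.label,
        "n_positions": len(pset.positions),
        "n_pairs": len(calls),
        "n_subset_shared": int(frame["subset_shared"].fillna(False).sum()),
        "outputs": ["subset_identity.tsv", "full_identity.tsv",
                    "specificity_calls.tsv"],
    }


def _run_classify(params: dict, outdir: Path, seed: int) -> dict:
    if "fasta" not in params:
        raise DataValidationError("classify stage needs a 'fasta' path")
    seqs = aln_mod.read_sequences(params["fasta"])
    table = ligand_mod.motif_presence_table(
        seqs,
        target_class=params.get("target_class", "DDWC_like"),
        k=int(params.get("k", 4)),
        hydrophobes=frozenset(params.get("hydrophobes", ligand_mod.DEFAULT_HYDROPHOBES)),
    )
    table.to_csv(outdir / "ligand_classes.tsv", sep="\t", index=False)
    counts = ligand_mod.class_counts(table)
    return {"n_sequences": len(table),
            "class_counts": counts.to_dict(),
            "output": "ligand_classes.tsv"}


def _run_screen_stats(params: dict, outdir: Path, seed: int) -> dict:
    source = params.get("table", "packaged:A")
    if isinstance(source, str) and source.startswith("packaged:"):
        table = screen_mod.packaged_table(source.split(":", 1)[1])
    else:
        table = screen_mod.load_hit_table(source)
    ranked = screen_mod.rank_prey(table)
    result = {
        "screen_label": table.screen_label,
        "records": len(table),
        "total_hits_weighted": screen_mod.total_hits(table),
        "top_colony_counts": [r.colonies for r in ranked[:2]],
        "terminal_distribution": screen_mod.terminal_distribution(table).to_dict(),
    }
    if "suffix" in params:
        result["suffix_count"] = screen_mod.count_suffix(table, params["suffix"])
    pd.DataFrame(
        [{"prey_id": r.prey_id, "cterm": r.cterm, "colonies": r.colonies}
         for r in ranked]
    ).to_csv(outdir / "screen_ranked.tsv", sep="\t", index=False)
    return result


def _run_logo(params: dict, outdir: Path, seed: int) -> dict:
    if "counts" not in params:
        raise DataValidationError("logo stage needs a 'counts' TSV path")
    table = logo_mod.PeptideCountTable.from_tsv(params["counts"])
    pfm = logo_mod.build_pfm(
        table, pseudocount=float(params.get("pseudocount", logo_mod.DEFAULT_PSEUDOCOUNT))
    )
    track = logo_mod.information_content(pfm)
    sig = logo_mod.signature(
        pfm, track,
        ic_threshold=float(params.get("ic_threshold", logo_mod.DEFAULT_IC_THRESHOLD)),
        freq_threshold=float(params.get("freq_threshold", logo_mod.DEFAULT_FREQ_THRESHOLD)),
    )
    pfm.frequencies.to_csv(outdir / "pfm.tsv", sep="\t")
    track.bits.rename("bits").to_csv(outdir / "information_content.tsv", sep="\t")
    if params.get("plot", False):
        ax = logo_mod.plot_logo(pfm)
        ax.figure.savefig(outdir / "logo.png", dpi=120)
    return {"signature": str(sig),
            "ic_bits": {int(k): float(v) for k, v in track.bits.items()},
            "outputs": ["pfm.tsv", "information_content.tsv"]}


def _run_coexpr(params: dict, outdir: Path, seed: int) -> dict:
    if "matrix" not in params:
        raise DataValidationError("coexpr stage needs a 'matrix' TSV path")
    m = coex_mod.MetacellExpressionMatrix.from_tsv(
        params["matrix"], params.get("annotation")
    )
    calls = coex_mod.binarize(m, threshold=float(params.get("threshold", 0.0)))
    celltype = params.get("celltype")
    result: dict = {"threshold": calls.threshold, "celltype": celltype}
    if "ref" in params and "candidates" in params and "control" in params:
        frame = coex_mod.calibration_compare(
            calls, params["ref"], list(params["candidates"]),
            params["control"], celltype,
        )
        frame.to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
        result["calibration"] = frame.to_dict(orient="records")
    if "venn" in params:
        a, b, d = params["venn"]
        result["venn"] = coex_mod.venn3(calls, a, b, d, celltype).as_dict()
    return result


def _run_assay(params: dict, outdir: Path, seed: int) -> dict:
    if "wells" not in params:
        raise DataValidationError("assay stage needs a 'wells' TSV path")
    wells = assay_mod.read_wells(params["wells"])
    control = params.get("control", "control")
    normalized = assay_mod.normalize_to_control(wells, control)
    normalized.to_csv(outdir / "normalized_activity.tsv", sep="\t", index=False)
    result = {"control": control,
              "conditions": normalized.to_dict(orient="records")}
    comparisons = [tuple(c) for c in params.get("comparisons", [])]
    if comparisons:
        tests = assay_mod.test_report(
            wells, control, comparisons,
            mode=params.get("mode", "two_sample"),
            alpha=float(params.get("alpha", 0.05)),
            bonferroni=bool(params.get("bonferroni", False)),
        )
        tests.to_csv(outdir / "assay_tests.tsv", sep="\t", index=False)
        result["tests"] = tests.to_dict(orient="records")
    return result


_STAGE_RUNNERS = {
    "trim": _run_trim,
    "sweep": _run_sweep,
    "simplot": _run_simplot,
    "specmatrix": _run_specmatrix,
    "classify": _run_classify,
    "screen_stats": _run_screen_stats,
    "logo": _run_logo,
    "coexpr": _run_coexpr,
    "assay": _run_assay,
}


def reproduce_table1_stats() -> dict:
    """Recompute the screen statistics from the packaged example tables.

    Screen A (tandem PDZ-1/PDZ-2/P1BM bait): colony-weighted total, colonies
    without a terminal valine, and the top two prey colony counts.  Screen B
    (PDZ-1 alone): colony-weighted total, top prey colony count, the
    colony-weighted WV-suffix count, and the number of unique prey with a
    terminal isoleucine once the top-ranked prey is excluded.
    """
    a = screen_mod.packaged_table("A")
    b = screen_mod.packaged_table("B")
    top_a = screen_mod.rank_prey(a)
    top_b = screen_mod.rank_prey(b)
    b_without_top = b.drop(top_b[0].prey_id, top_b[0].cterm)
    return {
        "screen_A": {
            "total_hits": screen_mod.total_hits(a),
            "non_terminal_V": screen_mod.count_terminal_residue(
                a, {"V"}, invert=True
            ),
            "top_two_colony_counts": [r.colonies for r in top_a[:2]],
        },
        "screen_B": {
            "total_hits": screen_mod.total_hits(b),
            "top_colony_count": top_b[0].colonies,
            "wv_suffix_hits": screen_mod.count_suffix(b, "WV"),
            "terminal_I_prey_excluding_top": screen_mod.count_terminal_residue(
                b_without_top, {"I"}, weighted=False
            ),
        },
    }
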
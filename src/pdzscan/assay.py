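"""β-galactosidase reporter quantification, normalization and t-tests.

Activity per well follows the Miller-style kit convention
``1000 · A420 / (t · V · OD600)`` (absorbance at 420 nm over incubation time
in minutes, culture volume in mL and culture density); the constant cancels
under normalization.  Condition summaries are reported relative to the mean
activity of a positive-control interaction, as mean ± sample SD over
replicate wells.  Condition contrasts use Welch's unequal-variance two-sample
t-test by default (pooled-variance available) or the paired t-test on
per-replicate differences; p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError


@dataclass(frozen=True)
class AssayWell:
    condition: str
    replicate: int
    a420: float
    od600: float
    t_min: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.a420 < 0:
            raise DataValidationError("A420 must be >= 0")
        for name, v in (("OD600", self.od600), ("time", self.t_min),
                        ("volume", self.volume_ml)):
            if v <= 0:
                raise DataValidationError(f"{name} must be > 0, got {v}")


def beta_gal_activity(w: AssayWell) -> float:
    """Activity units: 1000 · A420 / (t · V · OD600)."""
    return 1000.0 * w.a420 / (w.t_min * w.volume_ml * w.od600)


def read_wells(source) -> list[AssayWell]:
    """Load wells from a TSV with condition/replicate/A420/OD600/t_min/volume_ml."""
    df = pd.read_csv(source, sep="\t")
    required = {"condition", "replicate", "A420", "OD600", "t_min", "volume_ml"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"well table missing columns: {sorted(required - set(df.columns))}"
        )
    return [
        AssayWell(
            condition=str(r.condition), replicate=int(r.replicate),
            a420=float(r.A420), od600=float(r.OD600),
            t_min=float(r.t_min), volume_ml=float(r.volume_ml),
        )
        for r in df.itertuples()
    ]


def write_wells(wells: list[AssayWell], path) -> None:
    pd.DataFrame(
        [
            {
                "condition": w.condition, "replicate": w.replicate,
                "A420": w.a420, "OD600": w.od600,
                "t_min": w.t_min, "volume_ml": w.volume_ml,
            }
            for w in wells
        ]
    ).to_csv(path, sep="\t", index=False)


def normalize_to_control(wells: list[AssayWell], control: str) -> pd.DataFrame:
    """Per-condition mean ± SD of activity relative to the control mean.

    Every well's activity is divided by the control condition's mean activity,
    so the control row has mean exactly 1; SD is the sample SD (ddof=1, 0 for
    a single replicate).
    """
    by_cond: dict[str, list[float]] = {}
    for w in wells:
        by_cond.setdefault(w.condition, []).append(beta_gal_activity(w))
    if control not in by_cond:
        raise DataValidationError(f"control condition {control!r} not present")
    control_mean = float(np.mean(by_cond[control]))
    if control_mean == 0:
        raise DataValidationError("control mean activity is 0; cannot normalize")
    rows = []
    for cond, acts in by_cond.items():
        rel = np.asarray(acts) / control_mean
        rows.append(
            {
                "condition": cond,
                "mean": float(rel.mean()),
                "sd": float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
                "n": len(rel),
                "is_control": cond == control,
            }
        )
    return pd.DataFrame(rows)


def normalized_replicates(wells: list[AssayWell], control: str) -> dict[str, np.ndarray]:
    """Per-condition normalized replicate values (for downstream t-tests)."""
    by_cond: dict[str, list[float]] = {}
    for w in wells:
        by_cond.setdefault(w.condition, []).append(beta_gal_activity(w))
    if control not in by_cond:
        raise DataValidationError(f"control condition {control!r} not present")
    control_mean = float(np.mean(by_cond[control]))
    if control_mean == 0:
        raise DataValidationError("control mean activity is 0; cannot normalize")
    return {c: np.asarray(v) / control_mean for c, v in by_cond.items()}


def compare_conditions(
    a,
    b,
    mode: str = "two_sample",
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """(t statistic, degrees of freedom, two-sided p-value).

    ``two_sample`` uses Welch's unequal-variance test (Welch–Satterthwaite df)
    unless ``equal_var=True``; ``paired`` tests the per-pair differences.
    Identical groups give t = 0 (p reported as 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "two_sample":
        if len(a) < 2 or len(b) < 2:
            raise DataValidationError("two-sample test needs n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    elif mode == "paired":
        if len(a) != len(b):
            raise DataValidationError("paired test needs equal-length groups")
        if len(a) < 2:
            raise DataValidationError("paired test needs n >= 2 pairs")
        res = stats.ttest_rel(a, b)
    else:
        raise DataValidationError(f"unknown test mode {mode!r}")
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups, equal means
        t, p = 0.0, 1.0
    return t, float(res.df), p


def test_report(
    wells: list[AssayWell],
    control: str,
    comparisons: list[tuple[str, str]],
    mode: str = "two_sample",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run the requested condition contrasts on control-normalized replicates."""
    groups = normalized_replicates(wells, control)
    threshold = alpha / len(comparisons) if bonferroni and comparisons else alpha
    rows = []
    for x, y in comparisons:
        for label in (x, y):
            if label not in groups:
                raise DataValidationError(f"unknown condition {label!r}")
        t, df, p = compare_conditions(groups[x], groups[y], mode=mode)
        rows.append(
            {
                "a": x, "b": y, "t": t, "df": df, "p": p,
                "significant": p < threshold, "alpha_used": threshold,
            }
        )
    return pd.DataFrame(rows)
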
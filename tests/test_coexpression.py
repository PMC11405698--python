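"""Binary expression calls, Venn partitions and co-expression rates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pdzscan import (
    DataValidationError,
    MetacellExpressionMatrix,
    binarize,
    calibration_compare,
    count_expressing,
    pct_coexpression,
    venn3,
)
from pdzscan.simulate import gen_metacell_matrix


def matrix(values, genes, metacells, celltypes=None):
    return MetacellExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=metacells),
        celltypes=None if celltypes is None
        else pd.Series(celltypes, index=metacells),
    )


class TestBinarize:
    def test_all_zero_matrix_has_no_calls(self):
        m = matrix(np.zeros((2, 3)), ["g1", "g2"], ["m1", "m2", "m3"])
        assert binarize(m, 0.0).calls.values.sum() == 0

    def test_value_at_threshold_is_not_called(self):
        m = matrix([[1.0, 2.0]], ["g"], ["m1", "m2"])
        calls = binarize(m, 1.0).calls
        assert calls.loc["g"].tolist() == [0, 1]

    def test_matches_elementwise_oracle_on_random_matrix(self):
        rng = np.random.default_rng(2)
        vals = rng.random((5, 40))
        m = matrix(vals, [f"g{i}" for i in range(5)], [f"m{j}" for j in range(40)])
        calls = binarize(m, 0.3).calls.values
        expected = np.array(
            [[1 if vals[i, j] > 0.3 else 0 for j in range(40)] for i in range(5)]
        )
        assert (calls == expected).all()

    def test_negative_threshold_rejected(self):
        m = matrix(np.ones((1, 2)), ["g"], ["m1", "m2"])
        with pytest.raises(DataValidationError):
            binarize(m, -0.1)


class TestCountingAndFilters:
    def test_count_with_celltype_filter(self):
        m = matrix(
            [[1.0, 1.0, 0.0, 1.0]], ["g"], list("abcd"),
            celltypes=["neuron", "neuron", "neuron", "muscle"],
        )
        count, universe = count_expressing(binarize(m), "g", "neuron")
        assert (count, universe) == (2, 3)

    def test_unknown_gene_rejected(self):
        m = matrix(np.ones((1, 2)), ["g"], ["m1", "m2"])
        with pytest.raises(DataValidationError):
            count_expressing(binarize(m), "nope")

    def test_planted_prevalence_recovered(self):
        mat, gt = gen_metacell_matrix(
            n_metacells=1000, prevalence={"g": 0.3}, seed=7
        )
        count, universe = count_expressing(binarize(mat), "g")
        # 99% binomial interval around 300
        se = np.sqrt(0.3 * 0.7 * 1000)
        assert abs(count - 300) < 2.576 * se


class TestVenn3:
    def test_identical_rows_fall_in_triple_region(self):
        m = matrix(np.ones((3, 4)), ["a", "b", "c"], list("wxyz"))
        part = venn3(binarize(m), "a", "b", "c")
        assert part.abc == 4 and part.none == 0

    def test_mutually_exclusive_rows_populate_singletons(self):
        vals = np.eye(3)
        m = matrix(vals, ["a", "b", "c"], ["m1", "m2", "m3"])
        part = venn3(binarize(m), "a", "b", "c")
        assert (part.a_only, part.b_only, part.c_only) == (1, 1, 1)
        assert part.ab_only == part.ac_only == part.bc_only == part.abc == 0

    def test_duplicate_gene_labels_rejected(self):
        m = matrix(np.ones((2, 2)), ["a", "b"], ["m1", "m2"])
        with pytest.raises(DataValidationError):
            venn3(binarize(m), "a", "a", "b")

    def test_matches_per_unit_exhaustive_classification(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            vals = (rng.random((3, 50)) > 0.5).astype(float)
            m = matrix(vals, ["a", "b", "c"], [f"m{j}" for j in range(50)])
            part = venn3(binarize(m), "a", "b", "c")
            regions = {k: 0 for k in part.as_dict()}
            for j in range(50):
                key = (vals[0, j] > 0, vals[1, j] > 0, vals[2, j] > 0)
                name = {
                    (True, False, False): "A_only",
                    (False, True, False): "B_only",
                    (False, False, True): "C_only",
                    (True, True, False): "AB_only",
                    (True, False, True): "AC_only",
                    (False, True, True): "BC_only",
                    (True, True, True): "ABC",
                    (False, False, False): "none",
                }[key]
                regions[name] += 1
            assert part.as_dict() == regions

    def test_regions_partition_universe(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            vals = (rng.random((3, 60)) > rng.random()).astype(float)
            m = matrix(vals, ["a", "b", "c"], [f"m{j}" for j in range(60)])
            part = venn3(binarize(m), "a", "b", "c")
            assert part.universe == 60

    def test_counts_invariant_under_metacell_permutation(self):
        rng = np.random.default_rng(31)
        vals = (rng.random((3, 30)) > 0.4).astype(float)
        cols = [f"m{j}" for j in range(30)]
        m1 = matrix(vals, ["a", "b", "c"], cols)
        order = rng.permutation(30)
        m2 = matrix(vals[:, order], ["a", "b", "c"], [cols[i] for i in order])
        assert venn3(binarize(m1), "a", "b", "c") == venn3(binarize(m2), "a", "b", "c")


class TestCoexpressionRates:
    def test_self_coexpression_is_100(self):
        m = matrix([[1.0, 0.0], [1.0, 0.0]], ["r", "o"], ["m1", "m2"])
        assert pct_coexpression(binarize(m), "r", "r") == 100.0

    def test_never_expressed_partner_is_0(self):
        m = matrix([[1.0, 1.0], [0.0, 0.0]], ["r", "o"], ["m1", "m2"])
        assert pct_coexpression(binarize(m), "r", "o") == 0.0

    def test_undefined_when_ref_never_expressed(self):
        m = matrix([[0.0, 0.0], [1.0, 1.0]], ["r", "o"], ["m1", "m2"])
        with pytest.raises(DataValidationError):
            pct_coexpression(binarize(m), "r", "o")

    def test_consistent_with_venn_mass(self):
        rng = np.random.default_rng(37)
        vals = (rng.random((3, 80)) > 0.5).astype(float)
        m = matrix(vals, ["r", "o", "z"], [f"m{j}" for j in range(80)])
        calls = binarize(m)
        part = venn3(calls, "r", "o", "z")
        n_ref = int(calls.calls.loc["r"].sum())
        lhs = pct_coexpression(calls, "r", "o") * n_ref / 100.0
        rhs = part.ab_only + part.abc
        assert lhs == pytest.approx(rhs)

    def test_planted_conditional_rate_recovered(self):
        mat, _ = gen_metacell_matrix(
            n_metacells=4000,
            prevalence={"ref": 0.1, "other": 0.1},
            conditional={("ref", "other"): 0.18},
            seed=11,
        )
        calls = binarize(mat)
        pct = pct_coexpression(calls, "ref", "other")
        n_ref = int(calls.calls.loc["ref"].sum())
        half_width = 2.576 * np.sqrt(0.18 * 0.82 / n_ref) * 100
        assert abs(pct - 18.0) < half_width


class TestCalibrationCompare:
    def _design(self, seed=13):
        mat, _ = gen_metacell_matrix(
            n_metacells=4000,
            prevalence={"cav2c": 0.11, "mint": 0.1, "b1": 0.15, "b2": 0.01},
            conditional={
                ("cav2c", "mint"): 0.18,
                ("cav2c", "b1"): 0.19,
                ("cav2c", "b2"): 0.012,
            },
            celltype_fractions={"neuron": 0.8, "other": 0.2},
            seed=seed,
        )
        return binarize(mat)

    def test_candidate_near_control_is_flagged_comparable(self):
        report = calibration_compare(
            self._design(), "cav2c", ["mint", "b2"], "b1", "neuron"
        ).set_index("gene")
        assert report.loc["mint", "comparable_to_control"]
        assert report.loc["mint", "ratio_to_control"] == pytest.approx(
            18.0 / 19.0, rel=0.35
        )

    def test_rare_candidate_is_not_comparable(self):
        report = calibration_compare(
            self._design(), "cav2c", ["mint", "b2"], "b1", "neuron"
        ).set_index("gene")
        assert not report.loc["b2", "comparable_to_control"]
        assert report.loc["b2", "ratio_to_control"] < 0.2

    def test_control_has_ratio_exactly_one(self):
        report = calibration_compare(
            self._design(), "cav2c", ["mint"], "b1", "neuron"
        ).set_index("gene")
        assert report.loc["b1", "ratio_to_control"] == 1.0
        assert report.loc["b1", "comparable_to_control"]
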
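"""Alignment parsing, trimming, windowed similarity and position mapping."""

import numpy as np
import pytest

from pdzscan import (
    DataValidationError,
    RaggedAlignmentError,
    gap_fraction_profile,
    map_reference_positions,
    read_alignment,
    sweep_trim,
    trim_by_gap_threshold,
    windowed_similarity,
)
from pdzscan.alignment import AMINO_ACIDS

from conftest import random_alignment


class TestReadAlignment:
    def test_parses_rows_in_file_order(self):
        aln = read_alignment(">a\nAC-D\n>b\nAC-D")
        assert aln.n_rows == 2 and aln.length == 4
        assert aln.ids == ["a", "b"]

    def test_uppercases_residues(self):
        aln = read_alignment(">a\nacd-\n>b\nACDE")
        assert aln.rows[0].residues == "ACD-"

    @pytest.mark.parametrize(
        "text,exc",
        [
            (">a\nACDE\n>b\nACDEF", RaggedAlignmentError),
            (">a\nACDE\n>a\nACDE", DataValidationError),
            ("", DataValidationError),
            (">a\nAC!D\n>b\nACDE", DataValidationError),
        ],
    )
    def test_rejects_malformed_input(self, text, exc):
        with pytest.raises(exc):
            read_alignment(text)


class TestGapProfileAndTrim:
    def test_gap_fractions_by_hand(self):
        aln = read_alignment(">a\nA-\n>b\nA-\n>c\nA-\n>d\nAA")
        assert gap_fraction_profile(aln).tolist() == [0.0, 0.75]

    def test_trim_retains_columns_at_or_above_threshold(self, toy_alignment):
        trimmed, cols = trim_by_gap_threshold(toy_alignment, 0.9)
        assert cols == [0, 3]
        assert [r.residues for r in trimmed.rows] == ["AD", "AD"]

    def test_gt_zero_is_identity(self, toy_alignment):
        _, cols = trim_by_gap_threshold(toy_alignment, 0.0)
        assert cols == list(range(toy_alignment.length))

    def test_gt_one_with_gap_everywhere_empties_alignment(self):
        aln = read_alignment(">a\nA-\n>b\n-A")
        trimmed, cols = trim_by_gap_threshold(aln, 1.0)
        assert cols == [] and trimmed.length == 0

    def test_threshold_outside_unit_interval_rejected(self, toy_alignment):
        with pytest.raises(DataValidationError):
            trim_by_gap_threshold(toy_alignment, 1.5)

    def test_sweep_counts_match_individual_trims(self, toy_alignment):
        # non-gap fractions are (1, .5, 0, 1): column 1 falls below both
        # thresholds, so both retain exactly columns {0, 3}
        table = sweep_trim(toy_alignment, [0.6, 0.9])
        assert table["columns_retained"].tolist() == [2, 2]
        expected = [trim_by_gap_threshold(toy_alignment, gt)[1] for gt in (0.6, 0.9)]
        assert table["columns_retained"].tolist() == [len(c) for c in expected]

    def test_monotone_nesting_over_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            aln = random_alignment(rng, int(rng.integers(2, 7)), int(rng.integers(4, 30)))
            thresholds = sorted(rng.random(4))
            previous = None
            for gt in thresholds:
                _, cols = trim_by_gap_threshold(aln, gt)
                if previous is not None:
                    assert set(cols) <= set(previous)
                previous = cols


def brute_force_similarity(aln, matrix, window):
    """Independent double loop over pairs and windows."""
    n, L = aln.n_rows, aln.length
    col = []
    for j in range(L):
        total, pairs = 0.0, 0
        for i in range(n):
            for k in range(i + 1, n):
                a, b = aln.rows[i].residues[j], aln.rows[k].residues[j]
                pairs += 1
                if a in AMINO_ACIDS and b in AMINO_ACIDS:
                    total += matrix[(a, b)]
        col.append(total / pairs)
    half = (window - 1) // 2
    return [
        sum(col[c - half : c + half + 1]) / window
        for c in range(half, L - half)
    ]


class TestWindowedSimilarity:
    def test_identical_tryptophan_rows_score_matrix_diagonal(self, blosum62):
        track = windowed_similarity(read_alignment(">a\nWW\n>b\nWW"), blosum62, 1)
        assert track.values.tolist() == [11.0, 11.0]

    def test_gap_pairs_contribute_zero(self, blosum62):
        track = windowed_similarity(read_alignment(">a\nA-\n>b\nA-"), blosum62, 1)
        assert track.values.tolist() == [blosum62[("A", "A")], 0.0]

    def test_window_averages_constant_columns(self, blosum62):
        track = windowed_similarity(
            read_alignment(">a\nAAA\n>b\nAAA\n>c\nAAA"), blosum62, 3
        )
        assert np.allclose(track.values, blosum62[("A", "A")])

    def test_even_or_oversized_window_rejected(self, toy_alignment, blosum62):
        with pytest.raises(DataValidationError):
            windowed_similarity(toy_alignment, blosum62, 2)
        with pytest.raises(DataValidationError):
            windowed_similarity(toy_alignment, blosum62, 5)

    def test_agrees_with_brute_force_on_random_alignments(self, blosum62):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            L = int(rng.integers(3, 41))
            aln = random_alignment(rng, n, L)
            window = int(rng.choice([1, 3, 5]))
            if window > L:
                window = 1
            track = windowed_similarity(aln, blosum62, window)
            expected = brute_force_similarity(aln, blosum62, window)
            assert np.allclose(track.values, expected, atol=1e-9)

    def test_invariant_under_row_permutation(self, blosum62):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, 5, 20)
        from pdzscan import Alignment

        shuffled = Alignment([aln.rows[i] for i in (3, 0, 4, 1, 2)])
        t1 = windowed_similarity(aln, blosum62, 5)
        t2 = windowed_similarity(shuffled, blosum62, 5)
        assert np.allclose(t1.values, t2.values)


class TestMapReferencePositions:
    def test_maps_through_reference_gaps(self):
        aln = read_alignment(">ref\nA-CD\n>o\nAACD")
        assert map_reference_positions(aln, "ref", [1, 2, 3]) == [0, 2, 3]

    def test_gapless_reference_is_identity_shift(self):
        aln = read_alignment(">ref\nACDE\n>o\nACDE")
        assert map_reference_positions(aln, "ref", [3]) == [2]

    def test_out_of_range_position_names_offenders(self):
        aln = read_alignment(">ref\nACDE\n>o\nACDE")
        with pytest.raises(DataValidationError, match="5"):
            map_reference_positions(aln, "ref", [1, 5])

    def test_unknown_reference_rejected(self, toy_alignment):
        with pytest.raises(DataValidationError):
            map_reference_positions(toy_alignment, "nope", [1])

    def test_roundtrip_recovers_reference_residues(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 4, 30)
        ref = aln.rows[0]
        ungapped = ref.ungapped()
        positions = [1, len(ungapped) // 2 + 1, len(ungapped)]
        cols = map_reference_positions(aln, ref.id, positions)
        assert [ref.residues[c] for c in cols] == [ungapped[p - 1] for p in positions]
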
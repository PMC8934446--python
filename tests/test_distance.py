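"""Edit-matrix, border-minimum and banded-computation behaviour."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threegold.distance import (
    ROW,
    banded_sld,
    edit_matrix,
    full_matrix_cells,
    levenshtein,
    mirrored_sld,
    sld,
    strip_common_prefix,
)
from threegold.params import DistanceParams, WeightScheme

from conftest import brute_levenshtein, random_dna

dna = st.text(alphabet="ACGT", max_size=8)
UNIT = WeightScheme.unit()
PROHIB = WeightScheme(1, 5, 100)  # substitutions excluded from optimal paths


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,w,expected",
        [
            ("TAGCTAGC", "TAGTAGCT", UNIT, 2),  # one insertion + one deletion
            ("TAGCTAGC", "TAGTAGCT", PROHIB, 6),  # the same edits, weighted 1 + 5
            ("ACGT", "ACGT", PROHIB, 0),
            ("", "ACGT", UNIT, 4),  # border initialisation max(i, j)
            ("", "", UNIT, 0),
        ],
    )
    def test_worked_examples(self, a, b, w, expected):
        assert levenshtein(a, b, w) == expected

    def test_matches_recursive_oracle(self, rnd):
        for _ in range(300):
            a = random_dna(rnd, rnd.randint(0, 6))
            b = random_dna(rnd, rnd.randint(0, 6))
            assert levenshtein(a, b) == brute_levenshtein(a, b)

    def test_matches_edlib_on_longer_strings(self, rnd):
        for _ in range(100):
            a = random_dna(rnd, rnd.randint(1, 30))
            b = random_dna(rnd, rnd.randint(1, 30))
            assert levenshtein(a, b) == edlib.align(a, b, mode="NW")["editDistance"]

    def test_symmetric_under_joint_swap(self, rnd):
        # transposing the matrix exchanges the roles of insertion and deletion
        w = WeightScheme(1, 3, 2)
        wT = WeightScheme(3, 1, 2)
        for _ in range(50):
            a = random_dna(rnd, rnd.randint(0, 8))
            b = random_dna(rnd, rnd.randint(0, 8))
            assert levenshtein(a, b, w) == levenshtein(b, a, wT)

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError, match="non-DNA"):
            levenshtein("ACGU", "ACGT")

    def test_n_never_matches(self):
        assert levenshtein("N", "N") == 1
        assert levenshtein("ANA", "ANA") == 1

    def test_lowercase_normalised(self):
        assert levenshtein("acgt", "ACGT") == 0


class TestSld:
    def test_border_minimum_forgives_downstream_frameshift(self):
        out = sld("TAGCTAGC", "TAGTAGCT")
        assert out.value == 1
        assert out.corner_value == 2
        assert out.positions == ((ROW, 1),)

    def test_weighted_border_minimum_is_unreliable(self):
        # the documented failure: unweighted borders make the weighted
        # border minimum 3 where the true weighted cost of the single
        # internal error is 5 (a deletion)
        assert sld("TAGCTAGC", "TAGTAGCT", PROHIB).value == 3

    def test_identity_minimum_at_corner(self):
        out = sld("ACGTACGT", "ACGTACGT")
        assert out.value == 0 and out.positions == ((ROW, 0),)

    def test_never_exceeds_corner(self, rnd):
        for _ in range(200):
            a = random_dna(rnd, rnd.randint(0, 10))
            b = random_dna(rnd, rnd.randint(0, 10))
            out = sld(a, b)
            assert out.value <= out.corner_value
            assert out.positions

    def test_positions_achieve_value(self, rnd):
        for _ in range(50):
            a = random_dna(rnd, rnd.randint(1, 8))
            b = random_dna(rnd, rnd.randint(1, 8))
            m = edit_matrix(a, b)
            out = sld(a, b)
            for border, d in out.positions:
                cell = m[-1, len(b) - d] if border == ROW else m[len(a) - d, -1]
                assert cell == out.value


class TestStripCommonPrefix:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAT", "AAAG", ("T", "G")),
            ("ACGT", "ACGT", ("", "")),
            ("GATTA", "CATTA", ("GATTA", "CATTA")),
        ],
    )
    def test_examples(self, a, b, expected):
        assert strip_common_prefix(a, b) == expected

    def test_preserves_unit_distances(self, rnd):
        for _ in range(100):
            core_a = random_dna(rnd, rnd.randint(0, 6))
            core_b = random_dna(rnd, rnd.randint(0, 6))
            prefix = random_dna(rnd, rnd.randint(0, 6))
            a, b = prefix + core_a, prefix + core_b
            sa, sb = strip_common_prefix(a, b)
            assert levenshtein(a, b) == levenshtein(sa, sb)
            assert sld(a, b).value == sld(sa, sb).value


class TestBandedSld:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(dna, dna, st.integers(0, 4), st.integers(0, 4),
           st.sampled_from([UNIT, WeightScheme(1, 2, 4), WeightScheme(2, 1, 4)]))
    def test_agrees_with_full_matrix_or_proves_exceeded(self, a, b, tau, f, w):
        params = DistanceParams(tau=tau, frameshift=f, weights=w)
        out = banded_sld(a, b, params)
        full = sld(a, b, w)
        bound = max(params.h, 1)
        if out.exceeded:
            assert full.value >= bound
        else:
            assert out.value == full.value
            assert out.positions == full.positions

    def test_identity_is_never_exceeded(self):
        for tau, f in [(0, 0), (1, 0), (3, 4)]:
            out = banded_sld("ACGTACGTAC", "ACGTACGTAC", DistanceParams(tau=tau, frameshift=f))
            assert not out.exceeded and out.value == 0

    def test_all_mismatch_exceeds(self):
        out = banded_sld("AAAAAAAAAA", "CCCCCCCCCC", DistanceParams(tau=1, frameshift=1))
        assert out.exceeded

    def test_wide_band_falls_back_to_full_matrix(self, rnd):
        a, b = random_dna(rnd, 5), random_dna(rnd, 5)
        params = DistanceParams(tau=10, frameshift=10)
        out = banded_sld(a, b, params)
        assert not out.exceeded
        assert out.value == sld(a, b).value

    def test_computes_fewer_cells_than_full_matrix(self, rnd):
        params = DistanceParams(tau=3, frameshift=4, weights=WeightScheme(1, 2, 4))
        for n in (10, 20, 30):
            assert n > params.tau + 1
            a, b = random_dna(rnd, n), random_dna(rnd, n)
            out = banded_sld(a, b, params)
            assert out.cells_computed < full_matrix_cells(a, b)


class TestMirroredSld:
    def test_identity_both_zero(self):
        fwd, rev = mirrored_sld("ACGT", "ACGT")
        assert fwd.value == rev.value == 0

    def test_palindromes_agree(self):
        fwd, rev = mirrored_sld("ACGTGCA", "ACGTGCA"[::-1][::-1])
        a, b = "ATTA", "ACCA"  # both reverse to themselves
        fwd, rev = mirrored_sld(a, b)
        assert fwd.value == rev.value

    def test_min_never_above_forward(self, rnd):
        for _ in range(100):
            a, b = random_dna(rnd, 8), random_dna(rnd, 8)
            fwd, rev = mirrored_sld(a, b)
            assert min(fwd.value, rev.value) <= fwd.value

    def test_mirror_can_beat_the_forward_reading(self):
        # asymmetric error placement: reading these 20-mers reversed finds a
        # cheaper border interpretation than reading them as given
        a, b = "GACTGCCGCAGTTTCTCTTA", "TATACCCGAACTTTCTCCTA"
        fwd, rev = mirrored_sld(a, b)
        assert rev.value < fwd.value
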
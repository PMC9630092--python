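"""Threshold-scan tests: exact hypergeometric tails against enumeration,
scan geometry, selection rules and the permutation adjustment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionbench.threshold import (
    ScanInput,
    hypergeom_tail,
    permutation_adjust,
    scan_read_thresholds,
)


def enumeration_tail(a, b, c, d):
    """Independent oracle: exact-rational sum over all tables with the same
    margins whose below/discordant cell is >= a."""
    N, K, n = a + b + c + d, a + c, a + b
    total = comb(N, n)
    acc = Fraction(0)
    for k in range(a, min(n, K) + 1):
        acc += Fraction(comb(K, k) * comb(N - K, n - k), total)
    return float(acc)


class TestHypergeomTail:
    def test_degenerate_margin(self):
        assert hypergeom_tail(0, 5, 0, 7) == 1.0

    def test_small_table_against_enumeration(self):
        expected = (comb(4, 3) * comb(6, 1) + comb(4, 4) * comb(6, 0)) / comb(10, 4)
        assert hypergeom_tail(3, 1, 1, 5) == pytest.approx(expected, abs=1e-14)
        assert hypergeom_tail(3, 1, 1, 5) == pytest.approx(enumeration_tail(3, 1, 1, 5), abs=1e-14)

    def test_two_tails_overlap_at_point_mass(self):
        """P(X >= a) + P(X <= a) = 1 + P(X = a)."""
        for table in [(3, 1, 1, 5), (2, 2, 4, 4), (0, 3, 5, 2)]:
            a, b, c, d = table
            point = enumeration_tail(a, b, c, d) - enumeration_tail(a + 1, b - 1, c - 1, d + 1) \
                if b > 0 and c > 0 else enumeration_tail(a, b, c, d)
            upper = hypergeom_tail(a, b, c, d, "greater")
            lower = hypergeom_tail(a, b, c, d, "less")
            assert upper + lower == pytest.approx(1.0 + point, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(-1, 2, 3, 4)

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_enumeration_property(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert hypergeom_tail(a, b, c, d) == pytest.approx(
            enumeration_tail(a, b, c, d), abs=1e-12
        )


def _perfect_split_input():
    # reads 1..8 x 1e4; the three lowest discordant, the five highest concordant
    reads = [i * 10**4 for i in range(1, 9)]
    concordant = [False, False, False, True, True, True, True, True]
    return ScanInput.from_arrays(reads, concordant)


class TestScan:
    def test_perfectly_separated_example(self):
        result = scan_read_thresholds(_perfect_split_input(), alpha=0.05)
        assert result.selected_threshold == pytest.approx(3.5e4)
        best = min(result.candidates, key=lambda c: c.p)
        assert (best.a, best.b, best.c, best.d) == (3, 0, 0, 5)
        assert result.min_p == pytest.approx(1 / comb(8, 3), abs=1e-14)

    def test_candidate_count_is_distinct_values_minus_one(self):
        scan_input = ScanInput.from_arrays([10, 10, 20, 30, 30, 40], [True, False] * 3)
        result = scan_read_thresholds(scan_input)
        assert len(result.candidates) == 3  # 4 distinct values

    def test_all_concordant_selects_nothing(self):
        scan_input = ScanInput.from_arrays([1, 2, 3, 4], [True] * 4)
        result = scan_read_thresholds(scan_input)
        assert result.selected_threshold is None
        assert result.min_p == 1.0

    def test_scale_invariance(self):
        base = scan_read_thresholds(_perfect_split_input())
        scaled_input = ScanInput.from_arrays(
            [r * 10 for r in _perfect_split_input().total_reads],
            _perfect_split_input().concordant,
        )
        scaled = scan_read_thresholds(scaled_input)
        assert [c.p for c in scaled.candidates] == [c.p for c in base.candidates]
        assert scaled.selected_threshold == pytest.approx(10 * base.selected_threshold)

    @given(st.data())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_transform_invariance(self, data):
        """The p-profile depends on read-count ranks only."""
        n = data.draw(st.integers(5, 20))
        reads = data.draw(
            st.lists(st.integers(1, 10**6), min_size=n, max_size=n, unique=True)
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        base = scan_read_thresholds(ScanInput.from_arrays(reads, labels))
        transformed = scan_read_thresholds(
            ScanInput.from_arrays([r * r for r in reads], labels)  # strictly increasing on positives
        )
        assert [c.p for c in transformed.candidates] == pytest.approx(
            [c.p for c in base.candidates], abs=1e-12
        )
        assert transformed.min_p == pytest.approx(base.min_p, abs=1e-12)

    def test_min_group_restricts_candidates(self):
        scan_input = _perfect_split_input()
        wide = scan_read_thresholds(scan_input, min_group=1)
        narrow = scan_read_thresholds(scan_input, min_group=3)
        assert len(narrow.candidates) < len(wide.candidates)
        assert all(c.a + c.b >= 3 and c.c + c.d >= 3 for c in narrow.candidates)


class TestPermutationAdjust:
    def test_degenerate_input_gives_one(self):
        scan_input = ScanInput.from_arrays([1, 2, 3, 4], [True] * 4)
        assert permutation_adjust(scan_input, B=200, seed=0) == 1.0

    def test_deterministic_given_seed(self):
        scan_input = _perfect_split_input()
        p1 = permutation_adjust(scan_input, B=300, seed=5)
        p2 = permutation_adjust(scan_input, B=300, seed=5)
        assert p1 == p2

    def test_perfect_separation_is_significant(self):
        """Only a handful of the C(8,3)=56 labelings achieve the observed
        min-p, so the adjusted p stays well below 0.05 at B=2000."""
        p = permutation_adjust(_perfect_split_input(), B=2000, seed=1)
        assert p <= 0.05

    def test_rejects_small_B(self):
        with pytest.raises(ValueError):
            permutation_adjust(_perfect_split_input(), B=50)
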
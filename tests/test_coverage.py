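"""Spanning-count queries and the sliding-window support profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molecut.coverage import (
    IntervalIndex,
    ScanParams,
    build_interval_index,
    compute_support_profile,
    count_spanning,
    spanning_counts,
)
from molecut.molecules import Molecule

from _oracles import brute_count, brute_profile


def _index(intervals, contig="ctg1"):
    return build_interval_index(
        [Molecule(contig, s, e, f"B{i}-1", 10) for i, (s, e) in enumerate(intervals)]
    )


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 8_000), st.integers(1, 4_000)).map(
        lambda t: (t[0], t[0] + t[1])
    ),
    max_size=60,
)


class TestContainmentCounts:
    def test_empty_index_returns_zero_everywhere(self):
        index = IntervalIndex()
        assert count_spanning(index, "ctg1", 0, 1000) == 0

    def test_exact_containment_boundaries(self):
        index = _index([(0, 1000)])
        assert index.count("ctg1", 0, 1000) == 1
        assert index.count("ctg1", 0, 1001) == 0

    def test_window_boundary_inclusion(self):
        # molecule starting exactly at the window start is counted;
        # one starting a base inside is not
        index = _index([(100, 5000), (101, 5000)])
        assert index.count("ctg1", 100, 1100) == 1

    def test_unknown_contig_is_zero_not_error(self):
        index = _index([(0, 1000)])
        assert count_spanning(index, "missing", 0, 500) == 0

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_counts_match_brute_force(self, data):
        intervals = data.draw(intervals_strategy)
        index = _index(intervals)
        for _ in range(10):
            a = data.draw(st.integers(0, 12_000))
            b = a + data.draw(st.integers(1, 3_000))
            assert index.count("ctg1", a, b) == brute_count(intervals, a, b)


class TestSupportProfile:
    def test_short_contig_yields_empty_profile(self):
        profile = compute_support_profile(_index([]), "ctg1", 500, ScanParams(window=1000))
        assert len(profile.well_covered) == 0

    def test_uniform_deep_tiling_is_all_true(self):
        # 25 molecules each covering the whole contig with margin
        intervals = [(0, 10_000)] * 25
        profile = compute_support_profile(
            _index(intervals), "ctg1", 10_000, ScanParams(window=1000, min_spanning=20)
        )
        assert profile.well_covered.all()
        assert len(profile.well_covered) == 9_001

    def test_repeat_style_break_at_5000(self):
        # deep coverage, but every molecule either ends at 5000 or starts there:
        # windows strictly containing position 5000 cannot be spanned
        intervals = [(0, 5_000)] * 30 + [(5_000, 10_000)] * 30
        profile = compute_support_profile(
            _index(intervals), "ctg1", 10_000, ScanParams(window=1000, min_spanning=20)
        )
        wc = profile.well_covered
        assert wc[4_000] and wc[5_000]  # [4000,5000) and [5000,6000) are spanned
        assert not wc[4_001 : 5_000].any()  # windows overlapping the break are not

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_profile_matches_brute_force(self, data):
        intervals = data.draw(intervals_strategy)
        length = data.draw(st.integers(0, 12_000))
        window = data.draw(st.integers(1, 2_000))
        span = data.draw(st.integers(1, 30))
        params = ScanParams(window=window, min_spanning=span)
        profile = compute_support_profile(_index(intervals), "ctg1", length, params)
        np.testing.assert_array_equal(
            profile.well_covered, brute_profile(intervals, length, window, span)
        )

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotonic_in_span_and_window(self, data):
        intervals = data.draw(intervals_strategy)
        index = _index(intervals)
        length, window, span = 10_000, data.draw(st.integers(1, 1_500)), data.draw(
            st.integers(1, 25)
        )
        base = compute_support_profile(
            index, "ctg1", length, ScanParams(window=window, min_spanning=span)
        ).well_covered
        stricter = compute_support_profile(
            index, "ctg1", length, ScanParams(window=window, min_spanning=span + 5)
        ).well_covered
        assert not (stricter & ~base).any()  # well-covered set shrinks with span
        wider = compute_support_profile(
            index, "ctg1", length, ScanParams(window=window + 200, min_spanning=span)
        ).well_covered
        n = len(wider)
        assert not (wider & ~base[:n]).any()  # and with window size

    def test_bedgraph_counts_are_exact(self):
        intervals = [(0, 3_000), (500, 4_000), (500, 4_000)]
        index = _index(intervals)
        counts = spanning_counts(index, "ctg1", 5_000, 1_000)
        expected = [brute_count(intervals, i, i + 1_000) for i in range(4_001)]
        np.testing.assert_array_equal(counts, expected)
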
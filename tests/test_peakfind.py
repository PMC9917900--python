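import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosync import DegenerateInputError, PeakParams, find_peaks, peak_stats
from cardiosync.peakfind import _prune_by_distance

from conftest import make_trace
from oracles import oracle_find_peaks

LOOSE = PeakParams(min_height=0.0, min_distance=0.0)


class TestFindPeaksExamples:
    def test_too_short_trace_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            find_peaks(make_trace([0, 1]), LOOSE)

    def test_monotone_trace_has_no_peaks(self):
        assert find_peaks(make_trace(np.arange(10.0)), LOOSE).count == 0

    def test_two_strict_maxima(self):
        pl = find_peaks(make_trace([0, 1, 0, 2, 0]), PeakParams(0.5, 0.0))
        np.testing.assert_array_equal(pl.indices, [1, 3])
        np.testing.assert_array_equal(pl.heights, [1, 2])

    def test_distance_pruning_keeps_taller(self):
        # min_distance of 3 frames at dt=0.05 -> 0.15 s
        pl = find_peaks(make_trace([0, 1, 0, 2, 0]), PeakParams(0.5, 0.15))
        np.testing.assert_array_equal(pl.indices, [3])

    def test_plateau_yields_first_index(self):
        pl = find_peaks(make_trace([0, 2, 2, 2, 0]), LOOSE)
        np.testing.assert_array_equal(pl.indices, [1])

    def test_endpoints_are_never_peaks(self):
        assert find_peaks(make_trace([5, 0, 0, 0, 7]), LOOSE).count == 0

    def test_height_tie_prefers_earlier_index(self):
        pl = find_peaks(make_trace([0, 2, 0, 2, 0]), PeakParams(0.0, 0.15))
        np.testing.assert_array_equal(pl.indices, [1])

    def test_prominence_filter(self):
        # second peak sits on a shoulder of the first: prominence 1, height 2
        v = [0, 3, 1, 2, 0]
        all_peaks = find_peaks(make_trace(v), LOOSE)
        np.testing.assert_array_equal(all_peaks.indices, [1, 3])
        np.testing.assert_array_equal(all_peaks.prominences, [3, 1])
        pruned = find_peaks(make_trace(v), PeakParams(0.0, 0.0, min_prominence=2.0))
        np.testing.assert_array_equal(pruned.indices, [1])

    def test_times_follow_frame_interval(self):
        pl = find_peaks(make_trace([0, 1, 0, 1, 0], dt=0.1), LOOSE)
        np.testing.assert_allclose(pl.times, [0.1, 0.3])


class TestOracleAgreement:
    @pytest.mark.parametrize(
        "min_height,d_frames,min_prom",
        [(0.0, 1.0, None), (1.0, 2.0, None), (0.0, 3.0, 1.0), (2.0, 2.0, 2.0)],
    )
    def test_matches_exhaustive_oracle_short_traces(self, min_height, d_frames, min_prom):
        """Exhaustive agreement on every length-<=7 trace over 3 levels."""
        params = PeakParams(min_height, d_frames * 0.05, min_prom)
        for n in range(3, 8):
            for seq in itertools.product(range(3), repeat=n):
                got = find_peaks(make_trace(seq), params).indices.tolist()
                want = oracle_find_peaks(seq, min_height, d_frames, min_prom)
                assert got == want, f"seq={seq}"

    def test_matches_scipy_on_tie_free_traces(self):
        """On continuous traces (no ties/plateaus) the greedy tallest-first
        pruning coincides with scipy's find_peaks distance semantics."""
        from scipy.signal import find_peaks as scipy_find_peaks

        rng = np.random.default_rng(123)
        for _ in range(50):
            v = rng.uniform(0, 1, 60)
            for d in (2, 5, 9):
                got = find_peaks(
                    make_trace(v), PeakParams(0.0, d * 0.05)
                ).indices
                want, _ = scipy_find_peaks(v, distance=d)
                np.testing.assert_array_equal(got, want)


@st.composite
def short_traces(draw):
    n = draw(st.integers(3, 40))
    return draw(
        st.lists(st.integers(0, 5), min_size=n, max_size=n).map(
            lambda xs: np.array(xs, dtype=float)
        )
    )


class TestProperties:
    @given(short_traces())
    @settings(max_examples=200, deadline=None)
    def test_distance_pruning_is_idempotent(self, v):
        accepted = find_peaks(make_trace(v), PeakParams(0.0, 0.15)).indices
        again = _prune_by_distance(accepted, v[accepted], 3.0)
        np.testing.assert_array_equal(again, accepted)

    @given(short_traces())
    @settings(max_examples=200, deadline=None)
    def test_min_height_monotonicity(self, v):
        counts = [
            find_peaks(make_trace(v), PeakParams(h, 0.0)).count
            for h in (0.0, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(short_traces())
    @settings(max_examples=200, deadline=None)
    def test_min_distance_monotonicity(self, v):
        counts = [
            find_peaks(make_trace(v), PeakParams(0.0, d * 0.05)).count
            for d in (1, 2, 4, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(short_traces(), st.integers(1, 10))
    @settings(max_examples=200, deadline=None)
    def test_time_shift_equivariance(self, v, k):
        """Prepending k flat baseline frames shifts peak indices by k."""
        base = find_peaks(make_trace(v), PeakParams(0.5, 0.1)).indices
        shifted_trace = np.concatenate([np.full(k, v[0]), v])
        shifted = find_peaks(make_trace(shifted_trace), PeakParams(0.5, 0.1)).indices
        np.testing.assert_array_equal(shifted, base + k)

    @given(short_traces())
    @settings(max_examples=100, deadline=None)
    def test_accepted_peaks_respect_filters(self, v):
        params = PeakParams(1.0, 0.15, min_prominence=1.0)
        pl = find_peaks(make_trace(v), params)
        assert np.all(np.diff(pl.indices) >= 3)
        assert np.all(pl.heights >= 1.0)
        assert np.all(pl.prominences >= 1.0)


class TestPeakStats:
    def test_uniform_spacing(self):
        pl = find_peaks(make_trace([0, 1, 0, 1, 0, 1, 0], dt=0.5), LOOSE)
        count, ibi, cv = peak_stats(pl, duration=3.5)
        assert count == 3
        assert ibi == pytest.approx(1.0)
        assert cv == pytest.approx(0.0)

    def test_no_peaks_is_undefined(self):
        pl = find_peaks(make_trace(np.zeros(5)), LOOSE)
        count, ibi, cv = peak_stats(pl, duration=1.0)
        assert count == 0
        assert np.isnan(ibi) and np.isnan(cv)

    def test_hand_computed_cv(self):
        # peaks at 0.0, 0.5, 1.5 s -> IBIs {0.5, 1.0}: mean 0.75, sd 0.25
        pl = find_peaks(make_trace([0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0,
                                    0, 0, 0, 0, 1, 0], dt=0.1), LOOSE)
        np.testing.assert_allclose(pl.times, [0.2, 0.7, 1.7])
        count, ibi, cv = peak_stats(pl, duration=1.9)
        assert count == 3
        assert ibi == pytest.approx(0.75)
        assert cv == pytest.approx(0.25 / 0.75)
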
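import numpy as np
import pytest

from cardiosync import (
    AnalysisUnavailableError,
    PeakParams,
    analyze_calcium_video,
    find_peaks,
    frequency_map,
    phase_map,
    reference_beats,
)
from cardiosync.peakfind import PeakList

from conftest import make_trace


def peaklist_from_times(times, dt=0.05):
    times = np.asarray(times, dtype=float)
    idx = np.round(times / dt).astype(np.int64)
    return PeakList(
        indices=idx,
        times=times,
        heights=np.ones_like(times),
        prominences=np.ones_like(times),
        frame_interval=dt,
    )


class TestFrequencyMap:
    def test_regular_train_closed_form(self):
        pl = peaklist_from_times(np.arange(21) * 0.5)  # 21 peaks over 10 s
        fm = frequency_map([pl], duration=10.0)
        assert fm.values_hz[0] == pytest.approx(2.0)
        assert fm.values_bpm[0] == pytest.approx(120.0)

    def test_single_peak_region_is_inactive(self):
        fm = frequency_map([peaklist_from_times([1.0])], duration=10.0)
        assert not fm.active[0]
        assert np.isnan(fm.values_hz[0])

    def test_jittered_train_matches_direct_recomputation(self):
        rng = np.random.default_rng(21)
        times = np.sort(np.cumsum(rng.uniform(0.3, 0.6, 25)))
        fm = frequency_map([peaklist_from_times(times)], duration=15.0)
        assert fm.values_hz[0] == pytest.approx(
            (len(times) - 1) / (times[-1] - times[0])
        )

    def test_impulse_train_exact_frequency(self):
        """A noiseless impulse train with period P frames at interval dt
        maps to exactly 1/(P*dt) Hz."""
        p, dt = 7, 0.04
        v = np.zeros(100)
        v[3::p] = 1.0
        pl = find_peaks(make_trace(v, dt=dt), PeakParams(0.5, 0.0))
        fm = frequency_map([pl], duration=100 * dt)
        assert fm.values_hz[0] == 1.0 / (p * dt)

    def test_bpm_view_is_exactly_60x(self):
        rng = np.random.default_rng(2)
        pls = [
            peaklist_from_times(np.sort(rng.uniform(0, 10, 8)))
            for _ in range(5)
        ]
        fm = frequency_map(pls, duration=10.0)
        np.testing.assert_array_equal(fm.values_bpm, fm.values_hz * 60.0)


class TestReferenceBeats:
    def test_synchronized_field_reference_counts_match(self, small_sync_sim):
        _, calcium, _, _ = small_sync_sim
        res = analyze_calcium_video(calcium)
        assert res.phase is not None
        n_ref = len(res.phase.reference_beats)
        region_counts = [pl.count for pl in res.peaklists]
        assert n_ref == int(np.median(region_counts))

    def test_silent_field_is_unavailable(self):
        with pytest.raises(AnalysisUnavailableError):
            reference_beats(make_trace(np.zeros(50)))

    def test_two_offset_populations_reference_in_between(self):
        """Whole-field peaks of two half-populations offset by 0.05 s lie
        between the populations' beat times."""
        from cardiosync.synthetic_data import transient_kernel

        dt, offset = 0.01, 0.05
        t = np.arange(0, 3, dt)
        beats_a = np.arange(0.5, 3, 0.5)          # early population
        beats_b = beats_a + offset                # late population
        trace_a = np.zeros_like(t)
        trace_b = np.zeros_like(t)
        for tk in beats_a:
            trace_a += transient_kernel(t - tk)
        for tk in beats_b:
            trace_b += transient_kernel(t - tk)
        params = PeakParams(0.2, 0.1)
        peaks_a = reference_beats(make_trace(trace_a, dt=dt), params)
        peaks_b = reference_beats(make_trace(trace_b, dt=dt), params)
        ref = reference_beats(
            make_trace(0.5 * trace_a + 0.5 * trace_b, dt=dt), params
        )
        assert len(ref) == len(peaks_a) == len(peaks_b)
        assert np.all(peaks_a <= ref) and np.all(ref <= peaks_b)


class TestPhaseMap:
    def test_self_reference_phase_zero(self):
        times = np.arange(1, 11) * 0.5
        pm = phase_map([peaklist_from_times(times)], times)
        assert pm.values_s[0] == pytest.approx(0.0, abs=1e-12)

    def test_earlier_region_has_positive_phase(self):
        ref = np.arange(1, 11) * 0.5
        pm = phase_map([peaklist_from_times(ref - 0.05)], ref)
        assert pm.values_s[0] == pytest.approx(+0.05)

    def test_later_region_has_negative_phase(self):
        ref = np.arange(1, 11) * 0.5
        pm = phase_map([peaklist_from_times(ref + 0.08)], ref)
        assert pm.values_s[0] == pytest.approx(-0.08)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(8)
        ref = np.sort(np.cumsum(rng.uniform(0.4, 0.6, 15)))
        region = ref + rng.uniform(-0.05, 0.05, 15)
        region = np.sort(region)
        fwd = phase_map([peaklist_from_times(region)], ref).values_s[0]
        rev = phase_map([peaklist_from_times(ref)], region).values_s[0]
        assert fwd == pytest.approx(-rev, abs=0.05)

    def test_unmatched_region_is_nan(self):
        ref = np.arange(1, 6) * 1.0
        pm = phase_map([peaklist_from_times([])], ref)
        assert np.isnan(pm.values_s[0])

    def test_phase_bounded_by_half_reference_interval(self):
        rng = np.random.default_rng(12)
        ref = np.arange(1, 21) * 0.5
        for _ in range(10):
            region = np.sort(rng.uniform(0, 10, 15))
            pm = phase_map([peaklist_from_times(region)], ref)
            v = pm.values_s[0]
            assert np.isnan(v) or abs(v) <= 0.25 + 1e-12


class TestSimulatedRecovery:
    def test_phase_gradient_recovered_with_matching_sign(self):
        """A left-to-right +0.08 -> 0 s lag gradient yields a phase map
        decreasing left to right with positive values on the left."""
        from cardiosync import SimParams, simulate_monolayer

        params = SimParams(
            height=96, width=96, n_frames=300, rate_bpm=90.0,
            phase_field=("gradient", 0.08, 0.0), seed=5,
        )
        calcium, _, truth = simulate_monolayer(params, include_motion=False)
        res = analyze_calcium_video(calcium)
        grid_phase = res.phase.values_s.reshape(res.grid.grid_shape)
        col_means = np.nanmean(grid_phase, axis=0)
        assert col_means[0] > col_means[-1]
        assert col_means[0] > 0.04
        # recovered lag within one frame interval of truth for most regions
        truth_grid = truth.phase_s.reshape(truth.grid_shape)
        # phase is relative to the population; align by removing the mean
        err = np.abs(
            (grid_phase - np.nanmean(grid_phase))
            - (truth_grid - truth_grid.mean())
        )
        assert np.median(err) < params.frame_interval

    def test_synchronized_sim_frequency_and_phase_errors_small(self, small_sync_sim):
        params, calcium, _, truth = small_sync_sim
        res = analyze_calcium_video(calcium)
        truth_hz = truth.rate_hz[0]
        err = np.abs(res.frequency.values_hz - truth_hz) / truth_hz
        assert np.median(err[res.frequency.active]) < 0.05
        assert np.nanmedian(np.abs(res.phase.values_s)) < params.frame_interval
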
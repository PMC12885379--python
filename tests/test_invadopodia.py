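import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgquant import invadopodia as inv
from drgquant import synthetic
from drgquant.invadopodia import IntensityTrace

from conftest import brute_force_runs


def make_trace(values, background=None, **kw):
    values = np.asarray(values, dtype=float)
    if background is None:
        background = np.zeros_like(values)
    return IntensityTrace(values=values, background=background, **kw)


class TestBackgroundSubtract:
    def test_elementwise(self):
        tr = make_trace([10, 12], background=[2, 2])
        np.testing.assert_array_equal(inv.background_subtract(tr), [8, 10])

    def test_values_equal_background(self):
        tr = make_trace([3, 3, 3], background=[3, 3, 3])
        np.testing.assert_array_equal(inv.background_subtract(tr), [0, 0, 0])

    def test_negatives_preserved(self):
        tr = make_trace([1.0, 5.0], background=[2.0, 2.0])
        np.testing.assert_array_equal(inv.background_subtract(tr), [-1.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="background"):
            IntensityTrace(values=np.ones(5), background=np.ones(4))

    def test_constant_background_leaves_events_unchanged(self, rng):
        # affine property: subtract-then-add a constant background is a no-op
        vals = rng.normal(10, 3, size=50)
        t1 = make_trace(vals)
        t2 = make_trace(vals + 7.5, background=np.full(50, 7.5))
        assert inv.analyze_trace(t1) == inv.analyze_trace(t2)


class TestMeanThreshold:
    def test_hand_arithmetic(self):
        corrected = np.array([1.0] * 4 + [5.0] * 4 + [1.0] * 12)
        assert inv.mean_threshold(corrected) == pytest.approx(1.8)  # (16·1 + 4·5)/20

    def test_constant_series_gives_zero_events(self):
        corrected = np.full(30, 4.2)
        thr = inv.mean_threshold(corrected)
        assert thr == pytest.approx(4.2)
        assert inv.detect_events(corrected, thr) == []

    def test_window_start_excludes_prefix(self):
        corrected = np.array([100.0] * 5 + [1.0] * 10)
        assert inv.mean_threshold(corrected, window_start=6) == pytest.approx(1.0)
        assert inv.mean_threshold(corrected, window_start=1) == pytest.approx(np.mean(corrected))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            inv.mean_threshold(np.ones(5), window_start=6)


class TestDetectEvents:
    def test_single_event_frames_5_to_8(self):
        corrected = np.array([1.0] * 4 + [5.0] * 4 + [1.0] * 12)
        events = inv.detect_events(corrected, inv.mean_threshold(corrected))
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame, ev.duration_minutes) == (5, 8, 20.0)

    def test_three_frame_run_is_not_an_event(self):
        corrected = np.array([0.0] * 8 + [5.0] * 3 + [0.0] * 9)
        assert inv.detect_events(corrected, inv.mean_threshold(corrected)) == []

    def test_twelve_frame_run_is_60_min(self):
        corrected = np.array([0.0] * 5 + [5.0] * 12 + [0.0] * 13)
        events = inv.detect_events(corrected, inv.mean_threshold(corrected))
        assert [e.duration_minutes for e in events] == [60.0]

    def test_boundary_touching_runs_count(self):
        corrected = np.array([5.0] * 4 + [0.0] * 16)
        events = inv.detect_events(corrected, 1.0)
        assert [(e.start_frame, e.end_frame) for e in events] == [(1, 4)]
        events = inv.detect_events(corrected[::-1], 1.0)
        assert [(e.start_frame, e.end_frame) for e in events] == [(17, 20)]

    def test_exactly_at_threshold_does_not_extend(self):
        corrected = np.array([0, 4, 4, 4, 2, 0, 0, 2], dtype=float)
        # threshold = mean = 2.0; frame 5 sits exactly at it and does not extend the run
        assert inv.detect_events(corrected, inv.mean_threshold(corrected)) == []
        # a frame exactly at the threshold is not above it
        assert inv.detect_events(np.array([3.0, 3, 3, 3]), 3.0) == []

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            inv.detect_events(np.ones(5), np.nan)

    @settings(max_examples=300, deadline=None)
    @given(
        values=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=60),
        min_consecutive=st.integers(min_value=1, max_value=6),
    )
    def test_matches_brute_force_oracle(self, values, min_consecutive):
        corrected = np.array(values, dtype=float)
        thr = float(np.mean(corrected))
        got = inv.detect_events(corrected, thr, min_consecutive=min_consecutive)
        expected = brute_force_runs(corrected, thr, min_consecutive)
        assert [(e.start_frame - 1, e.end_frame - 1) for e in got] == expected

    def test_durations_are_multiples_of_interval(self, rng):
        for _ in range(50):
            corrected = rng.normal(size=40)
            for ev in inv.detect_events(corrected, 0.0, interval_minutes=5.0):
                assert ev.duration_minutes % 5.0 == 0
                assert ev.duration_minutes >= 20.0


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "minutes,expected",
        [
            (20, "transient"),
            (25, "transient"),
            (30, "transient"),
            (35, "transient"),
            (40, "intermediate"),
            (45, "intermediate"),
            (50, "intermediate"),
            (55, "intermediate"),
            (60, "stable"),
            (65, "stable"),
            (70, "stable"),
            (120, "stable"),
        ],
    )
    def test_bands(self, minutes, expected):
        assert inv.classify_event(minutes) == expected

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            inv.classify_event(15)

    def test_partition_no_gaps_or_overlaps(self):
        # every achievable duration at 5-min sampling gets exactly one class
        for k in range(4, 40):
            assert inv.classify_event(5.0 * k) in {"transient", "intermediate", "stable"}
        # half-open bands close the 36-39 style gaps at non-5-min intervals
        assert inv.classify_event(39.9) == "transient"
        assert inv.classify_event(40.0) == "intermediate"
        assert inv.classify_event(59.9) == "intermediate"
        assert inv.classify_event(60.0) == "stable"


class TestAffineInvariance:
    @settings(max_examples=100, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        shift=st.floats(min_value=-1000, max_value=1000),
    )
    def test_event_calls_invariant_under_positive_affine(self, scale, shift):
        rng = np.random.default_rng(7)
        vals = rng.normal(10, 4, size=60)
        t1 = make_trace(vals)
        t2 = make_trace(scale * vals + shift)
        e1 = inv.analyze_trace(t1)
        e2 = inv.analyze_trace(t2)
        assert [(e.start_frame, e.end_frame) for e in e1] == [
            (e.start_frame, e.end_frame) for e in e2
        ]


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_noise_free_spans_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n_frames = 120
        events, cursor = [], 1
        while cursor < n_frames - 12:
            start = cursor + int(rng.integers(2, 8))
            length = int(rng.integers(4, 13))
            if start + length - 1 > n_frames:
                break
            events.append((start, length, 4.0))
            cursor = start + length + 1  # gap keeps runs maximal
        spec = synthetic.TraceSpec(n_frames=n_frames, events=events, noise_sd=0.0, seed=seed)
        trace, truth = synthetic.gen_lifeact_trace(spec)
        got = inv.analyze_trace(trace)
        expected = [(e["start_frame"], e["end_frame"]) for e in truth.planted["events"]]
        assert [(e.start_frame, e.end_frame) for e in got] == expected

    def test_detector_recovers_two_planted_events(self):
        spec = synthetic.TraceSpec(n_frames=60, events=[(10, 4, 5.0), (30, 12, 5.0)], noise_sd=0.0)
        trace, _ = synthetic.gen_lifeact_trace(spec)
        corrected = inv.background_subtract(trace)
        got = inv.detect_events(corrected, inv.mean_threshold(corrected))
        oracle = brute_force_runs(corrected, float(np.mean(corrected)))
        assert [(e.start_frame - 1, e.end_frame - 1) for e in got] == oracle
        assert [(e.start_frame, e.end_frame) for e in got] == [(10, 13), (30, 41)]


class TestCompileEvents:
    def _trace_with_event(self, start, length, drez_arrival, n_frames=60, seed=0):
        spec = synthetic.TraceSpec(
            n_frames=n_frames,
            events=[(start, length, 5.0)],
            noise_sd=0.0,
            drez_arrival_frame=drez_arrival,
            seed=seed,
        )
        return synthetic.gen_lifeact_trace(spec)[0]

    def test_event_inside_drez_block(self):
        trace = self._trace_with_event(start=30, length=6, drez_arrival=20)
        comp = inv.compile_events([trace], "g")
        assert comp.durations_at_drez == [30.0]

    def test_event_during_navigation(self):
        trace = self._trace_with_event(start=5, length=6, drez_arrival=40)
        comp = inv.compile_events([trace], "g")
        assert comp.durations_all == [30.0]
        assert comp.durations_at_drez == []

    def test_strict_majority_rule(self):
        # 6-frame event straddling arrival: 3 drez frames is not a majority
        trace = self._trace_with_event(start=10, length=6, drez_arrival=13)
        assert inv.compile_events([trace], "g").durations_at_drez == []
        # 4 of 6 frames at drez is
        trace = self._trace_with_event(start=10, length=6, drez_arrival=12)
        assert inv.compile_events([trace], "g").durations_at_drez == [30.0]

    def test_missing_state_rejected(self):
        trace = self._trace_with_event(start=10, length=6, drez_arrival=None)
        with pytest.raises(ValueError, match="state"):
            inv.compile_events([trace], "g")

    def test_at_drez_subset_of_all(self, rng):
        traces = [
            self._trace_with_event(
                start=int(rng.integers(5, 30)),
                length=int(rng.integers(4, 10)),
                drez_arrival=int(rng.integers(2, 50)),
                seed=i,
            )
            for i in range(10)
        ]
        comp = inv.compile_events(traces, "g")
        pool = list(comp.durations_all)
        for d in comp.durations_at_drez:
            pool.remove(d)  # raises if not a sub-multiset

    def test_group_means_recover_planted_cohorts(self, rng):
        # planted contrast mirroring long vs short at-DREZ formations
        def cohort(durations_min, seed0):
            traces = []
            for i, d in enumerate(durations_min):
                k = int(d / 5)
                traces.append(self._trace_with_event(20, k, drez_arrival=10, n_frames=80, seed=seed0 + i))
            return traces

        long_durs = [70, 65, 75, 70, 65, 70]
        short_durs = [40, 45, 40, 40, 45, 40]
        comp_long = inv.compile_events(cohort(long_durs, 0), "treated")
        comp_short = inv.compile_events(cohort(short_durs, 100), "control")
        assert np.mean(comp_long.durations_at_drez) == pytest.approx(np.mean(long_durs))
        assert np.mean(comp_short.durations_at_drez) == pytest.approx(np.mean(short_durs))


class TestBasalWidth:
    def test_rectangular_profile(self):
        # plateau spanning 1.9 µm plus half-spacing interpolation on each side = 2.0
        positions = np.arange(0, 8.01, 0.1)
        profile = np.where((positions >= 3.0) & (positions <= 4.9), 10.0, 0.0)
        assert inv.basal_width(profile, positions) == pytest.approx(2.0)

    def test_gaussian_fwhm(self):
        positions = np.arange(0, 8.001, 0.01)
        profile = 100 * np.exp(-0.5 * ((positions - 4.0) / 1.0) ** 2)
        expected = 2 * np.sqrt(2 * np.log(2))  # ≈ 2.355 for σ = 1 µm
        assert inv.basal_width(profile, positions) == pytest.approx(expected, abs=0.02)

    def test_flat_profile_flagged(self):
        assert inv.basal_width(np.full(10, 3.0), np.arange(10.0)) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_width_ordering_preserved(self, seed):
        widths = [0.5, 1.0, 2.0, 3.5]
        got = []
        for w in widths:
            profile, positions, _ = synthetic.gen_width_profile(w, seed=seed)
            got.append(inv.basal_width(profile, positions))
        assert got == sorted(got)
        np.testing.assert_allclose(got, widths, rtol=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            inv.basal_width(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        spec = synthetic.TraceSpec(n_frames=30, events=[(5, 6, 4.0)], drez_arrival_frame=15)
        trace, _ = synthetic.gen_lifeact_trace(spec)
        path = tmp_path / "trace.csv"
        inv.write_trace_csv(trace, path)
        back = inv.read_trace_csv(path)
        np.testing.assert_allclose(back.values, trace.values)
        np.testing.assert_allclose(back.background, trace.background)
        assert back.interval_minutes == trace.interval_minutes
        assert list(back.state) == list(trace.state)
        assert inv.analyze_trace(back) == inv.analyze_trace(trace)
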
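import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rorqualfmr import respiration
from rorqualfmr.respiration import (
    DetectionConfig,
    Surfacing,
    detect_breaths,
    detect_breaths_long,
    detect_breaths_short,
    find_surfacings,
    respiration_rate,
    sliding_shannon_entropy,
)

from conftest import match_events

FS = 10.0


def square_wave_depth(n_cycles=10, surface_s=6.0, deep_s=54.0, deep_m=5.0):
    cycle = np.r_[
        np.zeros(int(surface_s * FS)), np.full(int(deep_s * FS), deep_m)
    ]
    return np.tile(cycle, n_cycles)


class TestFindSurfacings:
    def test_square_wave_yields_short_surfacings(self):
        surfs = find_surfacings(square_wave_depth(), FS)
        assert len(surfs) == 10
        assert all(s.kind == "short" for s in surfs)
        assert all(s.duration == pytest.approx(6.0) for s in surfs)

    def test_continuous_shallow_run_is_one_long_surfacing(self):
        depth = np.full(300, 0.5)  # 30 s at 0.5 m
        surfs = find_surfacings(depth, FS)
        assert len(surfs) == 1
        assert surfs[0].kind == "long"

    def test_boundary_ten_seconds_is_short(self):
        depth = np.r_[np.full(100, 0.5), np.full(100, 5.0)]  # exactly 10 s
        surfs = find_surfacings(depth, FS)
        assert [s.kind for s in surfs] == ["short"]

    def test_always_deep_gives_empty_list(self):
        assert find_surfacings(np.full(1000, 8.0), FS) == []

    def test_single_sample_runs_discarded(self):
        depth = np.full(100, 5.0)
        depth[50] = 0.2
        assert find_surfacings(depth, FS) == []

    def test_empty_depth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_surfacings(np.array([]), FS)


def v_surfacing(n=60, roll_value=0.0):
    """A 6-s V-shaped surfacing with the depth minimum at its centre."""
    t = np.arange(n) / FS
    depth = 0.1 + np.abs(t - 3.0) * 0.3
    roll = np.full(n, roll_value)
    surf = Surfacing(start=0.0, end=n / FS, kind="short", i0=0, i1=n)
    return surf, depth, roll


class TestShortPathway:
    def test_level_roll_gives_one_breath_at_depth_minimum(self):
        surf, depth, roll = v_surfacing()
        events = detect_breaths_short(surf, depth, roll, FS)
        assert len(events) == 1
        assert events[0].time == pytest.approx(3.0, abs=0.1)
        assert events[0].method == "short-surfacing"

    def test_rolled_surfacing_yields_no_breath(self):
        surf, depth, roll = v_surfacing()
        roll[30] = np.pi / 2  # 90 deg mid-surfacing
        assert detect_breaths_short(surf, depth, roll, FS) == []

    @pytest.mark.parametrize("deg, expect", [(44.0, 1), (45.0, 1), (46.0, 0)])
    def test_roll_gate_boundary_inclusive(self, deg, expect):
        surf, depth, roll = v_surfacing(roll_value=np.deg2rad(deg))
        assert len(detect_breaths_short(surf, depth, roll, FS)) == expect

    def test_length_mismatch_rejected(self):
        surf, depth, _ = v_surfacing()
        with pytest.raises(ValueError, match="length"):
            detect_breaths_short(surf, depth, np.zeros(10), FS)


class TestShannonEntropy:
    def test_constant_signal_zero_entropy(self):
        accel = np.tile([[0.0], [0.0], [-1.0]], 500)
        trace = sliding_shannon_entropy(accel, FS)
        np.testing.assert_array_equal(trace.SE, 0.0)

    def test_uniform_sixteen_bin_window_is_four_bits(self):
        """Differenced values cycling uniformly through 16 distinct levels
        give exactly log2(16) = 4 bits in every full window."""
        fs = 8.0  # 2-s window -> 16 differences per window
        diffs = np.tile(np.arange(16.0), 6)
        x = np.r_[0.0, np.cumsum(diffs)] + 1.0
        trace = sliding_shannon_entropy(x[None, :], fs, window_s=2.0, n_bins=16)
        mid = slice(20, -20)
        np.testing.assert_allclose(trace.SE[mid], 4.0, atol=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_entropy_bounded_by_log2_bins(self, seed):
        rng = np.random.default_rng(seed)
        accel = rng.normal(size=(3, 300))
        trace = sliding_shannon_entropy(accel, FS, n_bins=16)
        assert np.all(trace.SE >= 0.0)
        assert np.all(trace.SE <= 4.0 + 1e-12)

    def test_offset_invariance(self):
        """Adding a constant to every channel does not change the trace
        (per-channel differencing removes offsets exactly)."""
        rng = np.random.default_rng(5)
        accel = rng.normal(size=(3, 400))
        a = sliding_shannon_entropy(accel, FS)
        b = sliding_shannon_entropy(accel + 7.3, FS)
        np.testing.assert_array_equal(a.SE, b.SE)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_shannon_entropy(np.zeros((3, 15)), FS, window_s=2.0)


def transient_record(transient_times, n=600, amp=0.25):
    """A 60-s flat record with breath-like broadband bursts injected."""
    rng = np.random.default_rng(0)
    accel = np.zeros((3, n))
    accel[2] = -1.0
    pulse = np.sin(np.pi * (np.arange(5) + 0.5) / 5)
    for tt in transient_times:
        j = int(tt * FS) - 2
        accel[2, j : j + 5] -= amp * pulse
        accel[:, j : j + 5] += 0.6 * amp * pulse * rng.uniform(-1, 1, (3, 5))
    return accel


class TestLongPathway:
    def test_two_transients_twenty_seconds_apart(self):
        accel = transient_record([20.0, 40.0])
        trace = sliding_shannon_entropy(accel, FS)
        surf = Surfacing(start=0.0, end=60.0, kind="long", i0=0, i1=600)
        events = detect_breaths_long(surf, trace)
        assert len(events) == 2
        assert events[0].time == pytest.approx(20.0, abs=1.0)
        assert events[1].time == pytest.approx(40.0, abs=1.0)

    def test_flat_entropy_no_breaths(self):
        accel = np.tile([[0.0], [0.0], [-1.0]], 600)
        trace = sliding_shannon_entropy(accel, FS)
        surf = Surfacing(start=0.0, end=60.0, kind="long", i0=0, i1=600)
        assert detect_breaths_long(surf, trace) == []

    def test_close_peaks_resolved_by_separation_rule(self):
        accel = transient_record([30.0, 32.0])
        trace = sliding_shannon_entropy(accel, FS)
        surf = Surfacing(start=0.0, end=60.0, kind="long", i0=0, i1=600)
        events = detect_breaths_long(surf, trace, min_interbreath_s=5.0)
        assert len(events) == 1

    def test_uncovered_surfacing_rejected(self):
        accel = transient_record([20.0])
        trace = sliding_shannon_entropy(accel, FS)
        surf = Surfacing(start=30.0, end=90.0, kind="long", i0=300, i1=900)
        with pytest.raises(ValueError, match="cover"):
            detect_breaths_long(surf, trace)

    def test_short_surfacing_rejected(self):
        surf = Surfacing(start=0.0, end=6.0, kind="short", i0=0, i1=60)
        accel = transient_record([3.0])
        trace = sliding_shannon_entropy(accel, FS)
        with pytest.raises(ValueError, match="long"):
            detect_breaths_long(surf, trace)


class TestDetectBreaths:
    def test_detected_breaths_satisfy_invariants(self, blue_2h):
        dep, _ = blue_2h
        res = detect_breaths(dep)
        times = np.array([b.time for b in res.breaths])
        assert np.all(np.diff(times) >= 5.0)
        for b in res.breaths:
            s = res.surfacings[b.surfacing_id]
            assert s.start <= b.time <= s.end

    def test_noise_free_record_recovers_exact_count(self):
        from rorqualfmr import synthetic

        sim = synthetic.SimConfig(seed=11, duration=7200.0, noise_sd=0.0, depth_noise_sd=0.0)
        dep, truth = synthetic.simulate_deployment(synthetic.SPECIES_PRESETS["blue"], sim)
        res = detect_breaths(dep)
        assert len(res.breaths) == truth.breath_times.size
        tp, recall, precision = match_events([b.time for b in res.breaths], truth.breath_times)
        assert recall == 1.0 and precision == 1.0

    def test_record_without_surfacings_is_empty(self):
        from rorqualfmr.tag_io import TagDeployment

        n = 6000
        dep = TagDeployment(
            id="deep",
            species="blue",
            fs=FS,
            time=np.arange(n) / FS,
            depth=np.full(n, 20.0),
            pitch=np.zeros(n),
            roll=np.zeros(n),
            heading=np.zeros(n),
            speed=np.ones(n),
            accel=np.vstack([np.zeros(n), np.zeros(n), -np.ones(n)]),
        )
        res = detect_breaths(dep)
        assert res.breaths == [] and res.n_long == 0


class TestRespirationRate:
    @pytest.mark.parametrize(
        "n, dur, expect",
        [
            (60, 3600.0, 1.0),
            (0, 3600.0, 0.0),
            # deployment-scale figure: 32,878 breaths over 460 h of
            # foraging-bout time is 1.191 breaths per minute
            (32_878, 460 * 3600.0, 1.191),
        ],
    )
    def test_rate_values(self, n, dur, expect):
        assert respiration_rate(n, dur) == pytest.approx(expect, abs=5e-4)

    def test_accepts_event_lists(self):
        assert respiration_rate([1.0, 2.0, 3.0], 60.0) == pytest.approx(3.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            respiration_rate(5, 0.0)
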
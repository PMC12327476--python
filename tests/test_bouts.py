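import numpy as np
import pytest

from rorqualfmr import bouts as bm
from rorqualfmr.bouts import (
    Bout,
    Dive,
    bout_angular_velocity,
    bout_speed,
    find_dives,
    fit_bout_threshold,
    segment_bouts,
)
from rorqualfmr.synthetic import simulate_surface_intervals

FS = 10.0


def square_dives(n=10, dive_s=100.0, surface_s=60.0, depth_m=50.0):
    cycle = np.r_[np.full(int(dive_s * FS), depth_m), np.full(int(surface_s * FS), 0.5)]
    return np.tile(cycle, n)


class TestFindDives:
    def test_square_wave_dive_count_and_duration(self):
        dives = find_dives(square_dives(), FS)
        assert len(dives) == 10
        for d in dives:
            assert d.duration == pytest.approx(100.0)
            assert d.max_depth == pytest.approx(50.0)

    def test_lunges_assigned_to_containing_dive(self):
        dives = find_dives(square_dives(), FS, lunge_times=[2 * 160.0 + 50.0])
        assert [d.lunge_count for d in dives] == [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]
        assert dives[2].foraging and not dives[0].foraging

    def test_post_dive_surface_interval(self):
        dives = find_dives(square_dives(), FS)
        assert dives[0].post_dive_surface_interval == pytest.approx(60.0)
        assert dives[-1].post_dive_surface_interval is None

    def test_shallow_record_has_no_dives(self):
        assert find_dives(np.full(1000, 1.5), FS) == []


class TestBoutThreshold:
    def test_degenerate_constant_intervals(self):
        thr = fit_bout_threshold(np.full(50, 120.0))
        assert thr.mu == pytest.approx(120.0)
        assert thr.sigma == pytest.approx(0.0)
        assert thr.threshold == pytest.approx(120.0)

    def test_clean_gaussian_matches_sample_moments(self):
        """With no contamination the trimmed fit agrees with the plain
        sample mean + 3 sd (to within the little the trimming removes)."""
        x = simulate_surface_intervals(10_000, 90.0, 15.0, contamination=0.0, seed=5)
        thr = fit_bout_threshold(x)
        oracle = x.mean() + 3 * x.std()
        assert thr.threshold == pytest.approx(oracle, abs=1.5)

    def test_contaminated_fit_recovers_bulk_threshold(self):
        """10% long gaps are trimmed away; threshold stays near mu + 3 sigma
        of the generating bulk (135 s)."""
        x = simulate_surface_intervals(10_000, 90.0, 15.0, contamination=0.1, gap_scale=600.0, seed=6)
        thr = fit_bout_threshold(x)
        assert thr.threshold == pytest.approx(135.0, abs=3.0)

    def test_threshold_monotone_in_spread(self):
        base = simulate_surface_intervals(2000, 90.0, 5.0, seed=7)
        wide = 90.0 + (base - 90.0) * 3.0
        assert fit_bout_threshold(wide).threshold > fit_bout_threshold(base).threshold

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_bout_threshold(np.full(9, 100.0))


def foraging_dive(start, dur=200.0, lunges=1):
    return Dive(start=start, end=start + dur, max_depth=50.0, lunge_count=lunges)


class TestSegmentBouts:
    def test_chained_dives_form_one_bout(self):
        dives = [foraging_dive(i * 300.0) for i in range(5)]  # 100-s gaps
        out = [b for b in segment_bouts(dives, threshold=300.0) if b.type == "foraging"]
        assert len(out) == 1
        assert out[0].start == 0.0 and out[0].end == pytest.approx(1400.0)

    def test_large_gap_splits_bouts(self):
        dives = [foraging_dive(0.0), foraging_dive(300.0)]
        dives += [foraging_dive(900.0), foraging_dive(1200.0)]  # 400-s gap before
        out = [b for b in segment_bouts(dives, threshold=300.0) if b.type == "foraging"]
        assert len(out) == 2

    def test_transition_excluded_from_non_foraging_start(self):
        """A 2-h gap with a 30-min transition leaves a 90-min non-foraging
        bout starting 30 min after the preceding foraging bout ends."""
        dives = [foraging_dive(0.0, dur=4000.0), foraging_dive(4000.0 + 7200.0, dur=4000.0)]
        out = segment_bouts(dives, threshold=300.0, transition_min=30)
        nf = [b for b in out if b.type == "non-foraging"]
        assert len(nf) == 1
        assert nf[0].start == pytest.approx(4000.0 + 1800.0)
        assert nf[0].duration == pytest.approx(5400.0)
        assert nf[0].transition_excluded == pytest.approx(30.0)

    def test_retention_rule(self):
        dives = [foraging_dive(0.0, dur=1800.0)]  # 30-min bout
        out = segment_bouts(dives, threshold=300.0)
        assert all(not b.retained for b in out)

    def test_overlapping_dives_rejected(self):
        dives = [foraging_dive(0.0, dur=400.0), foraging_dive(300.0)]
        with pytest.raises(ValueError, match="overlap"):
            segment_bouts(dives, threshold=300.0)

    def test_invalid_transition_rejected(self):
        with pytest.raises(ValueError, match="transition"):
            segment_bouts([foraging_dive(0.0)], threshold=300.0, transition_min=7)

    def test_bouts_tile_the_record_span(self):
        """Retained + discarded bouts + excluded transitions cover the span
        with no overlap."""
        dives = [foraging_dive(1000.0 + i * 300.0) for i in range(12)]
        dives += [foraging_dive(10_000.0 + i * 300.0, lunges=0) for i in range(3)]
        dives += [foraging_dive(16_000.0 + i * 300.0) for i in range(13)]
        out = segment_bouts(dives, threshold=300.0, transition_min=15, record_span=(0.0, 22_000.0))
        out = sorted(out, key=lambda b: b.start)
        covered = 0.0
        for a, b in zip(out, out[1:]):
            assert b.start >= a.end - 1e-9
        covered = sum(b.duration for b in out)
        transitions = sum(b.transition_excluded * 60.0 for b in out)
        assert covered + transitions == pytest.approx(22_000.0)

    def test_ground_truth_bouts_recovered_on_synthetic_record(self, blue_6h):
        dep, truth = blue_6h
        dives = find_dives(dep.depth, dep.fs, lunge_times=truth.lunge_times)
        intervals = [
            d.post_dive_surface_interval
            for d in dives
            if d.foraging and d.post_dive_surface_interval is not None
        ]
        thr = fit_bout_threshold(intervals)
        out = segment_bouts(dives, thr.threshold, record_span=(0.0, dep.duration))
        got = [(b.start, b.end) for b in out if b.type == "foraging"]
        want = [(s, e) for s, e, kind in truth.bout_intervals if kind == "foraging"]
        assert len(got) == len(want)
        for (gs, ge), (ws, we) in zip(got, want):
            assert gs == pytest.approx(ws, abs=2.0)
            assert ge == pytest.approx(we, abs=2.0)


class TestBoutKinematics:
    def setup_method(self):
        n = 6000  # 600 s
        self.time = np.arange(n) / FS
        self.depth = np.full(n, 10.0)
        self.speed = np.full(n, 2.0)
        self.heading = np.zeros(n)
        self.bout = Bout(type="foraging", start=0.0, end=600.0)

    def test_constant_speed_at_depth(self):
        assert bout_speed(self.bout, self.time, self.depth, self.speed, FS) == pytest.approx(2.0, rel=1e-3)

    def test_surface_time_dilutes_mean_speed(self):
        self.depth[: 3000] = 1.0  # half the bout above the 2-m speed cut
        v = bout_speed(self.bout, self.time, self.depth, self.speed, FS)
        assert v == pytest.approx(1.0, rel=1e-3)

    def test_zero_speed(self):
        self.speed[:] = 0.0
        assert bout_speed(self.bout, self.time, self.depth, self.speed, FS) == 0.0

    def test_no_samples_rejected(self):
        late = Bout(type="foraging", start=10_000.0, end=10_600.0)
        with pytest.raises(ValueError, match="samples"):
            bout_speed(late, self.time, self.depth, self.speed, FS)

    def test_constant_heading_zero_turning(self):
        assert bout_angular_velocity(self.bout, self.time, self.heading, FS) == 0.0

    def test_uniform_rotation_rate(self):
        """One full turn over 600 s is 2 pi / 600 rad/s."""
        h = np.linspace(-np.pi, np.pi, self.time.size, endpoint=False)
        w = bout_angular_velocity(self.bout, self.time, h, FS)
        assert w == pytest.approx(2 * np.pi / 600.0, rel=1e-3)

    def test_oscillation_matches_brute_force_sum(self):
        h = 0.1 * np.sin(2 * np.pi * 0.5 * self.time)
        w = bout_angular_velocity(self.bout, self.time, h, FS)
        oracle = np.sum(np.abs(np.diff(h))) / 600.0
        assert w == pytest.approx(oracle, rel=1e-12)

    def test_wraparound_counts_short_way(self):
        """A heading sitting at the +/- pi seam accumulates only the small
        wrapped steps, not 2-pi jumps."""
        h = np.where(np.arange(self.time.size) % 2 == 0, np.pi - 0.01, -np.pi + 0.01)
        w = bout_angular_velocity(self.bout, self.time, h, FS)
        per_step = 0.02
        oracle = per_step * (self.time.size - 1) / 600.0
        assert w == pytest.approx(oracle, rel=1e-6)
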
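import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoalscope import (
    Bout,
    adjust_and_summarize,
    classify_pair_motion,
    detect_bouts,
    group_mean_speed,
    passing_by_duration,
    pbdur_mc_oracle,
    speed_profile,
)
from shoalscope.kinematics import PairDistanceSeries
from .conftest import make_group


def _series(d, fr=20.0, pair=("fish1", "fish2")):
    return PairDistanceSeries(pair=pair, d=np.asarray(d, float), frame_rate=fr)


def oracle_bouts(d, dist_cutoff, dur_cutoff, fr):
    """Brute-force run-length oracle: walk the series frame by frame."""
    out, start = [], None
    for t, val in enumerate(d):
        if val <= dist_cutoff and start is None:
            start = t
        elif val > dist_cutoff and start is not None:
            if (t - start) / fr >= dur_cutoff:
                out.append((start, t))
            start = None
    if start is not None and (len(d) - start) / fr >= dur_cutoff:
        out.append((start, len(d)))
    return out


class TestGroupMeanSpeed:
    def test_constant_speeds(self, arena):
        n = 200
        pos = np.zeros((n, 4, 2))
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            pos[:, i, 0] = np.arange(n) * v / 20.0
            pos[:, i, 1] = 5.0 + 5.0 * i
        rec = make_group(pos)
        assert group_mean_speed(rec) == pytest.approx(2.5)


class TestPassingByModel:
    def test_printed_substitutions(self):
        assert passing_by_duration(1.0).pbdur == pytest.approx(5.0)
        assert passing_by_duration(2.5).pbdur == pytest.approx(2.0)

    def test_closed_form_fields(self):
        m = passing_by_duration(2.0, cutoff=5.0)
        assert m.expected_relative_speed == pytest.approx(2.0 * 4 / np.pi)
        assert m.expected_chord == pytest.approx(5.0 * 4 / np.pi)
        assert m.pbdur * m.V == pytest.approx(m.cutoff)

    def test_stationary_group_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            passing_by_duration(0.0)

    def test_monte_carlo_oracle_recovers_ratio(self):
        mc = pbdur_mc_oracle(V=2.0, radius=5.0, n_draws=100_000, seed=42)
        assert abs(mc.ratio_times_v - 5.0) < 3 * mc.ratio_times_v_se
        assert abs(mc.e_chord - 20 / np.pi) < 3 * mc.e_chord_se
        assert abs(mc.e_relspeed - 8 / np.pi) < 3 * mc.e_relspeed_se


class TestDetectBouts:
    def test_always_close_single_bout(self):
        bouts = detect_bouts(_series(np.full(6000, 3.0)))
        assert len(bouts) == 1
        assert bouts[0].raw_duration == pytest.approx(300.0)

    def test_never_close_no_bouts(self):
        assert detect_bouts(_series(np.full(6000, 10.0))) == []

    def test_duration_threshold_boundary(self):
        base = np.full(300, 10.0)
        d79 = base.copy()
        d79[100:179] = 3.0
        assert detect_bouts(_series(d79)) == []
        d80 = base.copy()
        d80[100:180] = 3.0
        bouts = detect_bouts(_series(d80))
        assert len(bouts) == 1
        assert (bouts[0].start_frame, bouts[0].end_frame) == (100, 180)
        assert bouts[0].raw_duration == pytest.approx(4.0)

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            d = rng.uniform(0, 12, size=400)
            got = [(b.start_frame, b.end_frame) for b in detect_bouts(_series(d))]
            assert got == oracle_bouts(d, 5.0, 4.0, 20.0)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 10, 500)
        a = detect_bouts(_series(d, pair=("f1", "f2")))
        b = detect_bouts(_series(d, pair=("f2", "f1")))
        assert [(x.start_frame, x.end_frame) for x in a] == [
            (x.start_frame, x.end_frame) for x in b
        ]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_cutoff_monotonicity(self, seed):
        d = np.random.default_rng(seed).uniform(0, 10, 300)
        n_base = len(detect_bouts(_series(d), 5.0, 4.0))
        assert len(detect_bouts(_series(d), 6.0, 4.0)) >= n_base
        assert len(detect_bouts(_series(d), 5.0, 3.0)) >= n_base


class TestAdjustAndSummarize:
    def test_single_bout_contribution(self):
        bouts = [Bout(("f1", "f2"), 0, 200, 10.0)]
        adj, s = adjust_and_summarize(bouts, 2.0, ["f1", "f2", "f3", "f4"])
        assert adj[0].adjusted_duration == pytest.approx(8.0)
        assert s.total_adjusted_duration == {"f1": 8.0, "f2": 8.0, "f3": 0.0, "f4": 0.0}
        assert s.bout_count["f1"] == 1 and s.bout_count["f3"] == 0

    def test_adjustment_floors_at_zero(self):
        bouts = [Bout(("f1", "f2"), 0, 80, 4.0)]
        adj, _ = adjust_and_summarize(bouts, 5.0, ["f1", "f2"])
        assert adj[0].adjusted_duration == 0.0

    def test_random_sets_match_accumulation_oracle(self):
        rng = np.random.default_rng(10)
        ids = ["f1", "f2", "f3", "f4"]
        for _ in range(20):
            bouts = []
            for _ in range(rng.integers(0, 15)):
                i, j = rng.choice(4, 2, replace=False)
                raw = float(rng.uniform(4, 30))
                bouts.append(Bout((ids[i], ids[j]), 0, 1, raw))
            pb = float(rng.uniform(0, 8))
            _, s = adjust_and_summarize(bouts, pb, ids)
            expect = {f: 0.0 for f in ids}
            for b in bouts:
                for f in b.pair:
                    expect[f] += max(0.0, b.raw_duration - pb)
            for f in ids:
                assert s.total_adjusted_duration[f] == pytest.approx(expect[f])

    def test_monotone_in_pbdur(self):
        bouts = [Bout(("f1", "f2"), 0, 1, 10.0), Bout(("f1", "f3"), 0, 1, 6.0)]
        ids = ["f1", "f2", "f3", "f4"]
        totals = [
            adjust_and_summarize(bouts, pb, ids)[1].total_adjusted_duration["f1"]
            for pb in (0.0, 2.0, 5.0, 8.0, 12.0)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert min(totals) >= 0.0


class TestSpeedProfile:
    def test_constant_speed_fish_all_windows_equal(self, arena):
        n = 2000
        pos = np.zeros((n, 4, 2))
        for i in range(4):
            pos[:, i, 0] = np.arange(n) * 0.1  # 2 cm/s
            pos[:, i, 1] = 2.0 + 2 * i
        rec = make_group(pos, arena=arena)
        bouts = [Bout(("fish1", "fish2"), 500, 700, 10.0, 8.0)]
        prof = speed_profile(rec, "fish1", bouts)
        for v in (prof.before, prof.during, prof.after, prof.out):
            assert v == pytest.approx(2.0)

    def test_no_bouts_out_equals_overall_mean(self, arena):
        rng = np.random.default_rng(14)
        pos = np.cumsum(rng.normal(0, 0.02, (500, 4, 2)), axis=0) + 10.0
        rec = make_group(pos)
        prof = speed_profile(rec, "fish1", [])
        from shoalscope import speed_series

        assert prof.n_bouts == 0
        assert np.isnan(prof.during) and np.isnan(prof.before)
        assert prof.out == pytest.approx(
            float(speed_series(rec.trajectories[0]).mean())
        )


class TestClassifyPairMotion:
    def _two_fish_group(self, p1, p2, arena_size=200.0):
        n = len(p1)
        pos = np.zeros((n, 4, 2))
        pos[:, 0] = p1
        pos[:, 1] = p2
        pos[:, 2] = [100.0, 100.0]
        pos[:, 3] = [110.0, 110.0]
        from shoalscope import ArenaSpec

        return make_group(pos, arena=ArenaSpec(arena_size, arena_size))

    def test_leader_follower(self):
        n = 40
        t = np.arange(n) * 0.2
        p1 = np.column_stack([t + 5.0, np.full(n, 10.0)])  # ahead
        p2 = np.column_stack([t, np.full(n, 10.0)])
        rec = self._two_fish_group(p1, p2)
        labels = classify_pair_motion(rec, ("fish1", "fish2"))
        assert set(labels) == {"fish1_leads"}
        labels_swapped = classify_pair_motion(rec, ("fish2", "fish1"))
        assert set(labels_swapped) == {"fish2_leads"}

    def test_inverse_pass(self):
        n = 40
        t = np.arange(n) * 0.2
        p1 = np.column_stack([t, np.full(n, 10.0)])
        p2 = np.column_stack([20.0 - t, np.full(n, 11.0)])
        rec = self._two_fish_group(p1, p2)
        labels = classify_pair_motion(rec, ("fish1", "fish2"))
        assert set(labels) == {"inverse_pass"}

    def test_gather_at_45_degrees_matches_hand_computation(self):
        n = 20
        t = np.arange(n) * 0.2
        p1 = np.column_stack([t, t]) + 10.0
        p2 = np.column_stack([20.0 - t, t + 10.0])
        rec = self._two_fish_group(p1, p2)
        labels = classify_pair_motion(rec, ("fish1", "fish2"))
        # hand oracle, first window: dd = |p1-p2| change < -0.5; cos phi = 0
        d0 = np.hypot(*(p1[0] - p2[0]))
        d1 = np.hypot(*(p1[19] - p2[19]))
        assert d1 - d0 < -0.5
        assert labels[0] == "gather"
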
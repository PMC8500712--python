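import numpy as np
import pytest

from shoalscope import (
    ArenaSpec,
    Trajectory,
    iid_per_frame,
    nnd_per_frame,
    occupancy_probability,
    pairwise_distances,
    position_index,
    speed_series,
    total_distance,
    turning_angles,
    turning_bias_index,
)
from shoalscope.kinematics import TurningSeries
from .conftest import make_group


def _traj(positions, fr=20.0):
    positions = np.asarray(positions, dtype=float)
    return Trajectory("f1", positions, np.zeros(len(positions), bool), fr)


class TestDistances:
    def test_square_corners(self, square_group):
        ds = pairwise_distances(square_group)
        assert len(ds) == 6
        values = sorted(d.d[0] for d in ds)
        expect = sorted([10, 10, 10, 10, 10 * np.sqrt(2), 10 * np.sqrt(2)])
        np.testing.assert_allclose(values, expect)

    def test_coincident_fish_all_zero(self, arena):
        rec = make_group(np.ones((10, 4, 2)) * 3.0, arena=arena)
        for d in pairwise_distances(rec):
            np.testing.assert_array_equal(d.d, 0.0)

    def test_matches_brute_force_double_loop(self, arena):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 25, (40, 4, 2))
        rec = make_group(pos, arena=arena)
        got = {tuple(sorted(d.pair)): d.d for d in pairwise_distances(rec)}
        for i in range(4):
            for j in range(i + 1, 4):
                oracle = np.array(
                    [np.hypot(*(pos[t, i] - pos[t, j])) for t in range(40)]
                )
                key = tuple(sorted((f"fish{i+1}", f"fish{j+1}")))
                np.testing.assert_allclose(got[key], oracle)

    def test_iid_square_value_and_consistency(self, square_group):
        iid = iid_per_frame(square_group)
        assert iid[0] == pytest.approx((40 + 20 * np.sqrt(2)) / 6)
        mean_of_pairs = np.mean([d.d for d in pairwise_distances(square_group)], axis=0)
        np.testing.assert_allclose(iid, mean_of_pairs)

    def test_nnd_square_and_bound(self, square_group, arena):
        assert nnd_per_frame(square_group)[0] == pytest.approx(10.0)
        rng = np.random.default_rng(4)
        rec = make_group(rng.uniform(0, 25, (60, 4, 2)), arena=arena)
        assert np.all(nnd_per_frame(rec) <= iid_per_frame(rec) + 1e-12)

    def test_rigid_motion_invariance(self, arena):
        rng = np.random.default_rng(5)
        pos = rng.uniform(5, 20, (30, 4, 2))
        rec = make_group(pos, arena=arena)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = make_group(pos @ R.T + np.array([2.0, 1.0]), arena=ArenaSpec(100, 100))
        np.testing.assert_allclose(iid_per_frame(rec), iid_per_frame(moved), atol=1e-9)
        np.testing.assert_allclose(nnd_per_frame(rec), nnd_per_frame(moved), atol=1e-9)


class TestSpeedAndPath:
    def test_constant_speed(self):
        pos = np.column_stack([np.arange(100) * 0.1, np.zeros(100)])
        np.testing.assert_allclose(speed_series(_traj(pos)), 2.0)

    def test_stationary(self):
        np.testing.assert_allclose(speed_series(_traj(np.ones((50, 2)))), 0.0)

    def test_sine_path_matches_difference_oracle(self):
        t = np.arange(200) / 20.0
        pos = np.column_stack([t, np.sin(t)])
        got = speed_series(_traj(pos))
        # independent central-difference oracle on interior frames
        oracle = np.hypot(
            (pos[2:, 0] - pos[:-2, 0]) * 10.0, (pos[2:, 1] - pos[:-2, 1]) * 10.0
        )
        np.testing.assert_allclose(got[1:-1], oracle, rtol=1e-10)

    def test_total_distance_straight_and_consistency(self):
        pos = np.column_stack([np.arange(6000) * 0.1, np.zeros(6000)])
        tr = _traj(pos)
        assert total_distance(tr) == pytest.approx(599.9)
        # piecewise-constant integral of speed over interior ~ path length
        sp = speed_series(tr)
        assert total_distance(tr) == pytest.approx(sp.sum() / 20.0, rel=1e-2)


class TestRegions:
    def test_centre_pinned_fish(self, arena):
        pos = np.tile([arena.width / 2, arena.height / 2], (10, 1))
        assert position_index(_traj(pos), arena) == 1.0

    def test_corner_pinned_fish(self, arena):
        assert position_index(_traj(np.zeros((10, 2)) + 0.1), arena) == 0.0

    def test_uniform_occupancy_is_half(self, arena):
        rng = np.random.default_rng(11)
        pos = rng.uniform([0, 0], [arena.width, arena.height], (100_000, 2))
        assert position_index(_traj(pos), arena) == pytest.approx(0.5, abs=0.01)

    def test_occupancy_probability_extremes_and_uniform(self, arena):
        half = (0.0, 0.0, arena.width / 2, arena.height)
        inside = make_group(np.ones((20, 4, 2)) * 5.0, arena=arena)
        _, mean, _ = occupancy_probability(inside, half)
        assert mean == 1.0
        outside = make_group(np.ones((20, 4, 2)) * np.array([40.0, 5.0]), arena=arena)
        _, mean, _ = occupancy_probability(outside, half)
        assert mean == 0.0
        rng = np.random.default_rng(12)
        uni = make_group(
            rng.uniform([0, 0], [arena.width, arena.height], (20_000, 4, 2)),
            arena=arena,
        )
        _, mean, (lo, hi) = occupancy_probability(uni, half)
        assert mean == pytest.approx(0.5, abs=0.02)
        assert lo < 0.5 < hi


class TestTurning:
    def test_quarter_turn_sign(self):
        # +x displacement then +y displacement: anticlockwise quarter turn
        pos = np.array([[0, 0], [1, 0], [1, 1]], float)
        ts = turning_angles(_traj(pos), step=1)
        assert ts.theta[0] == pytest.approx(np.pi / 2)
        # same path sampled at the default 5-frame step
        dense = np.concatenate([
            np.linspace([0, 0], [1, 0], 6)[:-1],
            np.linspace([1, 0], [1, 1], 6),
        ])
        ts5 = turning_angles(_traj(dense), step=5)
        assert ts5.theta[0] == pytest.approx(np.pi / 2)

    def test_straight_line_zero_turns(self):
        pos = np.column_stack([np.arange(100.0), np.arange(100.0)])
        ts = turning_angles(_traj(pos))
        np.testing.assert_allclose(ts.theta, 0.0, atol=1e-12)
        assert ts.n_cw == ts.n_acw == 0

    def test_matches_rotation_oracle(self):
        rng = np.random.default_rng(21)
        v = rng.normal(0, 1, (500, 2, 2))
        pos = np.zeros((500, 3, 2))
        pos[:, 1] = v[:, 0]
        pos[:, 2] = v[:, 0] + v[:, 1]
        for k in range(50):
            ts = turning_angles(_traj(pos[k]), step=1)
            v1, v2 = v[k]
            # oracle: rotate the frame so v1 lies on +x, read off v2's angle
            a1 = np.arctan2(v1[1], v1[0])
            rot = np.array([[np.cos(-a1), -np.sin(-a1)], [np.sin(-a1), np.cos(-a1)]])
            w = rot @ v2
            assert ts.theta[0] == pytest.approx(np.arctan2(w[1], w[0]), abs=1e-10)

    def test_stationary_steps_excluded(self):
        pos = np.array([[0, 0], [1, 0], [1, 0], [1, 0], [2, 0]], float)
        ts = turning_angles(_traj(pos), step=1)
        assert ts.n_cw + ts.n_acw <= int(ts.valid.sum())
        assert not ts.valid[1]  # zero displacement in the middle

    def test_balanced_zigzag_index_zero(self):
        # alternating +30/-30 degree turns
        angles = np.cumsum([0] + [np.pi / 6 * (-1) ** k for k in range(41)])
        pos = np.cumsum(
            np.column_stack([np.cos(angles), np.sin(angles)]), axis=0
        )
        ts = turning_angles(_traj(pos), step=1)
        assert ts.n_cw == ts.n_acw
        assert turning_bias_index(ts) == 0.0

    def test_index_values(self):
        ts = TurningSeries("f", np.array([]), np.array([]), 200, 200)
        assert turning_bias_index(ts) == 0.0
        ts = TurningSeries("f", np.array([]), np.array([]), 100, 25)
        assert turning_bias_index(ts) == pytest.approx(abs(np.log2(100.5 / 25.5)))

    def test_circle_matches_closed_form(self):
        n_steps = 80
        ang = np.linspace(0, 4 * np.pi, n_steps + 2)
        pos = np.column_stack([np.cos(ang), np.sin(ang)]) * 8.0
        ts = turning_angles(_traj(pos), step=1)
        assert ts.n_cw == 0 and ts.n_acw == n_steps
        assert turning_bias_index(ts) == pytest.approx(np.log2((n_steps + 0.5) / 0.5))

    def test_reflection_invariance_of_index(self):
        rng = np.random.default_rng(30)
        steps = rng.normal(0, 1, (300, 2))
        pos = np.cumsum(steps, axis=0)
        mirrored = pos * np.array([1.0, -1.0])
        ts = turning_angles(_traj(pos), step=1)
        tm = turning_angles(_traj(mirrored), step=1)
        np.testing.assert_allclose(ts.theta, -tm.theta, atol=1e-12)
        assert ts.n_cw == tm.n_acw and ts.n_acw == tm.n_cw
        assert turning_bias_index(ts) == pytest.approx(turning_bias_index(tm))
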
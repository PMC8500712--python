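import numpy as np
import pytest

from shoalscope import ArenaSpec, GroupRecording, Trajectory


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


def make_group(positions: np.ndarray, frame_rate: float = 20.0,
               arena: ArenaSpec | None = None, group_id: str = "g") -> GroupRecording:
    """Build a GroupRecording from an (n_frames, 4, 2) position array."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    trajs = [
        Trajectory(f"fish{i + 1}", positions[:, i], np.zeros(n, dtype=bool), frame_rate)
        for i in range(4)
    ]
    return GroupRecording(group_id, trajs, arena or ArenaSpec())


@pytest.fixture
def square_group(arena) -> GroupRecording:
    """Four fish pinned at the corners of a 10 cm square for 100 frames."""
    corners = np.array([[5.0, 5.0], [15.0, 5.0], [15.0, 15.0], [5.0, 15.0]])
    pos = np.tile(corners, (100, 1, 1))
    return make_group(pos, arena=arena)


@pytest.fixture(scope="session")
def null_cohort():
    """Six non-interacting simulated groups, shared across tests."""
    from shoalscope import SimulationParams, simulate_cohort

    recs = simulate_cohort(SimulationParams(duration_s=120.0), n_groups=6, seed=7)
    return [r.filled() for r in recs]
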
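"""Reading, validation, repair and writing of four-fish trajectory data.

Recordings are per-frame X-Y coordinate tables produced by video tracking
(one row per fish per frame; frames where a fish's ID was lost are simply
absent).  The unit of analysis is a :class:`GroupRecording`: four equal-length
trajectories swimming in one arena.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "GroupRecording",
    "read_group",
    "write_group",
    "trim_lead_in",
    "fill_gaps",
    "load_config",
    "TELEPORT_CM",
]

# Displacement between consecutive observed frames above which we warn about
# a likely identity switch left uncorrected upstream.
TELEPORT_CM = 20.0


@dataclass(frozen=True)
class ArenaSpec:
    """Recording arena geometry and acquisition parameters.

    Distances in cm; the default matches a 50.8 x 25.4 cm tank filmed at
    20 frames per second.  ``px_per_cm`` converts pixel input to cm when set.
    ``region_masks`` maps a name to an axis-aligned rectangle
    ``(x0, y0, x1, y1)`` in cm, e.g. the equal-area central region or the
    lighted half of the arena.
    """

    width: float = 50.8
    height: float = 25.4
    frame_rate: float = 20.0
    px_per_cm: float | None = None
    region_masks: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena width and height must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive when given")
        for name, (x0, y0, x1, y1) in self.region_masks.items():
            if not (0 <= x0 <= x1 <= self.width and 0 <= y0 <= y1 <= self.height):
                raise ValueError(f"region mask {name!r} exceeds arena bounds")

    def centre_region(self) -> tuple[float, float, float, float]:
        """Concentric rectangle similar to the arena with exactly half its area.

        Scaling each axis by 1/sqrt(2) is the unique similar concentric
        rectangle whose area equals the peripheral remainder.
        """
        s = 1.0 / np.sqrt(2.0)
        w, h = self.width * s, self.height * s
        cx, cy = self.width / 2.0, self.height / 2.0
        return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


@dataclass
class Trajectory:
    """Per-frame positions of one fish.

    ``positions`` is an (n, 2) float array in cm (origin top-left, y down —
    the image convention; all metrics downstream are origin/axis invariant).
    ``missing_mask`` flags frames where the tracker lost the fish; those
    positions are NaN until :func:`fill_gaps` and the mask is preserved as
    provenance afterwards.
    """

    fish_id: str
    positions: np.ndarray
    missing_mask: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.positions) != len(self.missing_mask):
            raise ValueError("positions and missing_mask lengths differ")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def is_filled(self) -> bool:
        return not np.isnan(self.positions).any()


@dataclass
class GroupRecording:
    """Four same-length trajectories recorded together in one arena."""

    group_id: str
    trajectories: list[Trajectory]
    arena: ArenaSpec
    population_label: str = "synthetic"
    condition_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trajectories) != 4:
            raise ValueError(
                f"expected 4 fish, got {len(self.trajectories)}"
            )
        ids = [t.fish_id for t in self.trajectories]
        if len(set(ids)) != 4:
            raise ValueError(f"fish ids must be distinct, got {ids}")
        n = {t.n_frames for t in self.trajectories}
        if len(n) != 1:
            raise ValueError(f"inconsistent frame counts across fish: {sorted(n)}")
        fr = {t.frame_rate for t in self.trajectories}
        if len(fr) != 1:
            raise ValueError("inconsistent frame rates across fish")

    @property
    def n_frames(self) -> int:
        return self.trajectories[0].n_frames

    @property
    def frame_rate(self) -> float:
        return self.trajectories[0].frame_rate

    @property
    def fish_ids(self) -> list[str]:
        return [t.fish_id for t in self.trajectories]

    def positions_array(self) -> np.ndarray:
        """Stack positions as an (n_frames, 4, 2) array."""
        return np.stack([t.positions for t in self.trajectories], axis=1)

    def filled(self) -> "GroupRecording":
        """Return a copy with every trajectory gap-filled."""
        return dataclasses.replace(
            self, trajectories=[fill_gaps(t) for t in self.trajectories]
        )


def read_group(
    path: str | Path,
    arena: ArenaSpec,
    group_id: str | None = None,
    population_label: str = "synthetic",
    condition_labels: dict[str, str] | None = None,
) -> GroupRecording:
    """Read a trajectory CSV (``frame,fish_id,x,y``) into a GroupRecording.

    Missing rows (frames without an observation for a fish) become masked
    frames with NaN positions.  Pixel coordinates are converted to cm when the
    arena carries a ``px_per_cm`` calibration.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame", "fish_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"missing columns: {sorted(required - set(df.columns))} in {path}"
        )
    fish_ids = sorted(df["fish_id"].astype(str).unique())
    if len(fish_ids) != 4:
        raise ValueError(f"expected 4 fish, found {len(fish_ids)} in {path}")

    scale = 1.0 / arena.px_per_cm if arena.px_per_cm else 1.0
    f0, f1 = int(df["frame"].min()), int(df["frame"].max())
    n = f1 - f0 + 1
    trajectories = []
    for fid in fish_ids:
        sub = df[df["fish_id"].astype(str) == fid].sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int) - f0
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"duplicate frames for fish {fid} in {path}")
        pos = np.full((n, 2), np.nan)
        pos[frames, 0] = sub["x"].to_numpy(dtype=float) * scale
        pos[frames, 1] = sub["y"].to_numpy(dtype=float) * scale
        mask = np.ones(n, dtype=bool)
        mask[frames] = False
        traj = Trajectory(fid, pos, mask, arena.frame_rate)
        _warn_teleports(traj)
        trajectories.append(traj)

    return GroupRecording(
        group_id=group_id or path.stem,
        trajectories=trajectories,
        arena=arena,
        population_label=population_label,
        condition_labels=condition_labels or {},
    )


def write_group(rec: GroupRecording, path: str | Path) -> None:
    """Write the standard trajectory CSV; masked frames are omitted."""
    rows = []
    for traj in rec.trajectories:
        obs = ~traj.missing_mask
        frames = np.nonzero(obs)[0]
        rows.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "fish_id": traj.fish_id,
                    "x": traj.positions[frames, 0],
                    "y": traj.positions[frames, 1],
                }
            )
        )
    out = pd.concat(rows).sort_values(["frame", "fish_id"])
    out.to_csv(path, index=False, float_format="%.6f")


def trim_lead_in(rec: GroupRecording, seconds: float) -> GroupRecording:
    """Drop the first ``seconds`` of the recording from every trajectory.

    The lead-in contains the release of the fish into the arena and is
    discarded before analysis (60 s by convention).
    """
    n_trim = int(np.floor(seconds * rec.frame_rate))
    if n_trim > rec.n_frames:
        raise ValueError(
            f"cannot trim {n_trim} frames from a {rec.n_frames}-frame recording"
        )
    new = [
        dataclasses.replace(
            t, positions=t.positions[n_trim:].copy(), missing_mask=t.missing_mask[n_trim:].copy()
        )
        for t in rec.trajectories
    ]
    return dataclasses.replace(rec, trajectories=new)


def fill_gaps(traj: Trajectory) -> Trajectory:
    """Fill missing-ID runs by constant-velocity straight-line interpolation.

    Between the flanking observed positions this is the unique trajectory with
    constant speed and heading.  Gaps touching the recording edge (no flank on
    one side) hold the nearest observed position constant.  Observed frames
    are untouched and the missing mask is preserved as provenance.
    """
    if not traj.missing_mask.any():
        return traj
    obs = np.nonzero(~traj.missing_mask)[0]
    if len(obs) == 0:
        raise ValueError(f"fish {traj.fish_id} missing for the entire recording")
    idx = np.arange(traj.n_frames)
    pos = traj.positions.copy()
    for k in range(2):
        pos[:, k] = np.interp(idx, obs, traj.positions[obs, k])
    return dataclasses.replace(traj, positions=pos)


def _warn_teleports(traj: Trajectory) -> None:
    obs = np.nonzero(~traj.missing_mask)[0]
    if len(obs) < 2:
        return
    consec = np.diff(obs) == 1
    step = np.linalg.norm(np.diff(traj.positions[obs], axis=0), axis=1)
    n_jump = int(np.sum(step[consec] > TELEPORT_CM))
    if n_jump:
        warnings.warn(
            f"fish {traj.fish_id}: {n_jump} frame-to-frame jumps exceed "
            f"{TELEPORT_CM} cm (possible uncorrected ID switches)",
            stacklevel=3,
        )


def load_config(path: str | Path) -> dict:
    """Load a study configuration (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
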
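"""Nearby-interaction bout detection and the passing-by-duration correction.

A "nearby interaction" is a pairwise proximity bout: two fish within the
distance cutoff (5 cm) for at least the duration cutoff (4 s).  Because two
independently swimming fish also spend time within 5 cm by chance, each
bout's duration is corrected by subtracting the expected passing-by duration
PbDur = R / V, where R is the distance cutoff and V the group's mean speed.

PbDur follows from two expectations over uniformly random angles: with both
fish at speed V and a heading difference theta ~ U(0, pi), the relative
speed is |Vr| = 2 V sin(theta/2) with mean 4V/pi; a straight pass through a
radius-R disk at chord angle omega ~ U(0, pi) covers |L| = 2 R sin(omega)
with mean 4R/pi.  Their ratio, E|L| / E|Vr| = R / V, is the mean transit
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GroupRecording
from .kinematics import PairDistanceSeries, pairwise_distances, speed_series

__all__ = [
    "PassingByModel",
    "Bout",
    "InteractionSummary",
    "SpeedProfile",
    "group_mean_speed",
    "passing_by_duration",
    "detect_bouts",
    "detect_group_bouts",
    "adjust_and_summarize",
    "speed_profile",
    "classify_pair_motion",
    "DIST_CUTOFF_CM",
    "DUR_CUTOFF_S",
]

DIST_CUTOFF_CM = 5.0
DUR_CUTOFF_S = 4.0


@dataclass(frozen=True)
class PassingByModel:
    """Chance-transit model for two independently swimming fish."""

    V: float                       # group mean speed, cm/s
    cutoff: float                  # interaction radius R, cm
    expected_relative_speed: float  # E|Vr| = 4 V / pi, cm/s
    expected_chord: float           # E|L| = 4 R / pi, cm
    pbdur: float                    # R / V, s


@dataclass(frozen=True)
class Bout:
    """One pairwise nearby-interaction event; frame span is half-open."""

    pair: tuple[str, str]
    start_frame: int
    end_frame: int
    raw_duration: float
    adjusted_duration: float | None = None


@dataclass(frozen=True)
class InteractionSummary:
    """Per-fish adjusted interaction totals for one group."""

    fish_ids: list[str]
    total_adjusted_duration: dict[str, float]
    bout_count: dict[str, int]
    V: float
    pbdur: float


@dataclass(frozen=True)
class SpeedProfile:
    """Mean speed of one fish inside/around its nearby-interaction bouts.

    Windows: ``before`` (the 4 s preceding a bout), ``during`` (bout frames),
    ``after`` (the 4 s following), ``out`` (everything else).  Means are NaN
    when a fish has no bouts (out then covers the whole recording).
    """

    fish_id: str
    before: float
    during: float
    after: float
    out: float
    n_bouts: int


def group_mean_speed(rec: GroupRecording) -> float:
    """Mean over the four fish of each fish's mean frame speed (cm/s)."""
    return float(
        np.mean([speed_series(t).mean() for t in rec.trajectories])
    )


def passing_by_duration(V: float, cutoff: float = DIST_CUTOFF_CM) -> PassingByModel:
    """Expected chance-transit duration PbDur = cutoff / V for a group at speed V."""
    if V <= 0:
        raise ValueError("PbDur undefined for a stationary group (V <= 0)")
    e_vr = V * 4.0 / np.pi
    e_l = cutoff * 4.0 / np.pi
    return PassingByModel(
        V=V,
        cutoff=cutoff,
        expected_relative_speed=e_vr,
        expected_chord=e_l,
        pbdur=cutoff / V,
    )


def detect_bouts(
    pd_series: PairDistanceSeries,
    dist_cutoff: float = DIST_CUTOFF_CM,
    dur_cutoff: float = DUR_CUTOFF_S,
) -> list[Bout]:
    """Maximal runs with distance <= cutoff lasting >= the duration cutoff.

    A run of k frames at frame rate f lasts k/f seconds; runs shorter than
    the cutoff are discarded.  Intervals are half-open [start, end).
    """
    close = pd_series.d <= dist_cutoff
    min_frames = int(np.ceil(dur_cutoff * pd_series.frame_rate))
    bouts = []
    for start, end in _runs(close):
        if end - start >= min_frames:
            bouts.append(
                Bout(
                    pair=pd_series.pair,
                    start_frame=int(start),
                    end_frame=int(end),
                    raw_duration=(end - start) / pd_series.frame_rate,
                )
            )
    return bouts


def _runs(mask: np.ndarray):
    """Start/end (half-open) of each maximal True run."""
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return zip(starts, ends)


def detect_group_bouts(
    rec: GroupRecording,
    dist_cutoff: float = DIST_CUTOFF_CM,
    dur_cutoff: float = DUR_CUTOFF_S,
) -> list[Bout]:
    """Bouts across all six pairs of a group, ordered by start frame."""
    bouts: list[Bout] = []
    for series in pairwise_distances(rec):
        bouts.extend(detect_bouts(series, dist_cutoff, dur_cutoff))
    return sorted(bouts, key=lambda b: (b.start_frame, b.pair))


def adjust_and_summarize(
    bouts: list[Bout], pbdur: float, fish_ids: list[str], V: float = float("nan")
) -> tuple[list[Bout], InteractionSummary]:
    """Subtract PbDur from each bout and accumulate per-fish totals.

    Each pairwise bout contributes its adjusted duration (floored at zero)
    to both participating fish; simultaneous bouts with different partners
    accumulate separately.
    """
    totals = {fid: 0.0 for fid in fish_ids}
    counts = {fid: 0 for fid in fish_ids}
    adjusted = []
    for b in bouts:
        adj = max(0.0, b.raw_duration - pbdur)
        adjusted.append(
            Bout(b.pair, b.start_frame, b.end_frame, b.raw_duration, adj)
        )
        for fid in b.pair:
            totals[fid] += adj
            counts[fid] += 1
    summary = InteractionSummary(
        fish_ids=list(fish_ids),
        total_adjusted_duration=totals,
        bout_count=counts,
        V=V,
        pbdur=pbdur,
    )
    return adjusted, summary


def speed_profile(
    rec: GroupRecording,
    fish_id: str,
    bouts: list[Bout],
    window: float = 4.0,
) -> SpeedProfile:
    """Mean speed of one fish before / during / after / outside its bouts.

    Frames are partitioned with "during" taking precedence: the flanking
    windows are truncated at the recording edges and exclude frames claimed
    by any bout; "out" is the remainder.
    """
    idx = rec.fish_ids.index(fish_id)
    speeds = speed_series(rec.trajectories[idx])
    n = rec.n_frames
    w = int(round(window * rec.frame_rate))

    mine = [b for b in bouts if fish_id in b.pair]
    during = np.zeros(n, dtype=bool)
    before = np.zeros(n, dtype=bool)
    after = np.zeros(n, dtype=bool)
    for b in mine:
        during[b.start_frame : b.end_frame] = True
    for b in mine:
        before[max(0, b.start_frame - w) : b.start_frame] = True
        after[b.end_frame : min(n, b.end_frame + w)] = True
    before &= ~during
    after &= ~during
    out = ~(during | before | after)

    def _mean(mask: np.ndarray) -> float:
        return float(speeds[mask].mean()) if mask.any() else float("nan")

    return SpeedProfile(
        fish_id=fish_id,
        before=_mean(before),
        during=_mean(during),
        after=_mean(after),
        out=_mean(out),
        n_bouts=len(mine),
    )


#: Pair-motion categories over short analysis windows.
MOTION_CLASSES = (
    "disperse",
    "inverse_pass",
    "gather",
    "fish1_leads",
    "fish2_leads",
    "none",
)


def classify_pair_motion(
    rec: GroupRecording,
    pair: tuple[str, str],
    window: float = 1.0,
    delta_cm: float = 0.5,
    align_cos: float = 0.5,
) -> list[str]:
    """Classify each non-overlapping window of a pair's relative motion.

    Per window, the distance change ``dd`` and the alignment ``cos phi``
    between the two fish's net displacement vectors decide the label:
    opposed headings (cos phi < -align_cos) are an inverse pass; shrinking
    distance (dd < -delta) with non-opposed headings is gathering; growing
    distance (dd > +delta) is dispersal; aligned headings at roughly constant
    distance mean one fish leads (whichever is ahead along the common
    heading); anything else is "none".  Thresholds are free parameters — the
    categories are descriptive, not fitted.
    """
    i = rec.fish_ids.index(pair[0])
    j = rec.fish_ids.index(pair[1])
    p1 = rec.trajectories[i].positions
    p2 = rec.trajectories[j].positions
    w = int(round(window * rec.frame_rate))
    labels = []
    for s in range(0, rec.n_frames - w + 1, w):
        e = s + w
        v1 = p1[e - 1] - p1[s]
        v2 = p2[e - 1] - p2[s]
        dd = float(
            np.linalg.norm(p1[e - 1] - p2[e - 1]) - np.linalg.norm(p1[s] - p2[s])
        )
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            labels.append("none")
            continue
        cosphi = float(np.dot(v1, v2) / (n1 * n2))
        if cosphi < -align_cos:
            labels.append("inverse_pass")
        elif dd < -delta_cm and cosphi > -align_cos:
            labels.append("gather")
        elif dd > delta_cm and cosphi > -align_cos:
            labels.append("disperse")
        elif cosphi > align_cos:
            heading = (v1 + v2) / np.linalg.norm(v1 + v2)
            gap = p1[s] - p2[s]
            labels.append("fish1_leads" if float(np.dot(gap, heading)) > 0 else "fish2_leads")
        else:
            labels.append("none")
    return labels
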
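"""Random-regrouping null ensemble and cutoff calibration.

The chance baseline for nearby interactions is built by regrouping: draw one
fish from each of four different recorded groups and treat the four
time-aligned trajectories as a virtual group.  No two members of such a group
ever swam in the same arena, so any proximity structure is what four
independent swimmers produce by chance.  Comparing actual groups against this
ensemble bin-by-bin (distances) or duration-by-duration (sub-cutoff run
lengths), with Holm-corrected Welch t-tests, yields the bands of significant
separation from which the distance and duration cutoffs are chosen
conservatively (second-longest significant distance, second-shortest
significant duration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GroupRecording, Trajectory
from .interactions import _runs
from .kinematics import pairwise_distances

__all__ = [
    "NullEnsemble",
    "CalibrationCurve",
    "build_null_groups",
    "distance_calibration",
    "duration_calibration",
    "select_cutoff",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass
class NullEnsemble:
    """Virtual four-fish groups assembled from fish that never co-swam.

    ``n_source_groups`` bounds the ensemble's independent information: members
    reuse the same source fish, so however many regroupings are drawn, the
    effective sample size for inference never exceeds the number of source
    groups.
    """

    members: list[GroupRecording]
    provenance: list[list[tuple[str, str]]]  # per member: (source_group, fish)
    seed: int | None
    n_source_groups: int | None = None

    @property
    def effective_n(self) -> int:
        bound = self.n_source_groups or len(self.members)
        return min(len(self.members), bound)


@dataclass
class CalibrationCurve:
    """Binned actual-vs-null comparison with Holm-adjusted p-values."""

    metric: str  # "distance" (cm) or "duration" (s)
    bin_labels: np.ndarray  # candidate cutoff values
    actual_mean: np.ndarray
    actual_ci: np.ndarray  # (k, 2) 95% CI over groups
    null_mean: np.ndarray
    null_ci: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    alpha: float = ALPHA
    selected_cutoff: float | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.p_holm < self.alpha

    @property
    def significant_bins(self) -> np.ndarray:
        return self.bin_labels[self.significant]


def build_null_groups(
    recordings: list[GroupRecording], n: int = 1280, seed: int | None = None
) -> NullEnsemble:
    """Assemble ``n`` virtual groups, each from 4 distinct source groups.

    Source-group quadruples are drawn uniformly without replacement within a
    member (compositions may repeat across members); one fish is drawn
    uniformly from each chosen group.  Trajectories are unmodified copies,
    time-aligned by frame index and truncated to the shortest recording.
    """
    if len(recordings) < 4:
        raise ValueError("need at least 4 source groups to build a null ensemble")
    n_frames = min(r.n_frames for r in recordings)
    rng = np.random.default_rng(seed)
    members, provenance = [], []
    for k in range(n):
        src = rng.choice(len(recordings), size=4, replace=False)
        picks = rng.integers(0, 4, size=4)
        trajs, prov = [], []
        for slot, (g, f) in enumerate(zip(src, picks)):
            t = recordings[g].trajectories[f]
            trajs.append(
                Trajectory(
                    fish_id=f"m{slot + 1}",
                    positions=t.positions[:n_frames].copy(),
                    missing_mask=t.missing_mask[:n_frames].copy(),
                    frame_rate=t.frame_rate,
                )
            )
            prov.append((recordings[g].group_id, t.fish_id))
        members.append(
            GroupRecording(
                group_id=f"null{k + 1:04d}",
                trajectories=trajs,
                arena=recordings[0].arena,
                population_label="null",
            )
        )
        provenance.append(prov)
    return NullEnsemble(
        members=members,
        provenance=provenance,
        seed=seed,
        n_source_groups=len(recordings),
    )


def _distance_freqs(rec: GroupRecording, edges: np.ndarray) -> np.ndarray:
    d = np.concatenate([p.d for p in pairwise_distances(rec)])
    counts, _ = np.histogram(d, bins=edges)
    return counts / d.size


def _run_counts(rec: GroupRecording, dist_cutoff: float, durations: np.ndarray) -> np.ndarray:
    """Per candidate duration d, how many sub-cutoff runs last >= d seconds
    (inverse-cumulative event counts, summed over the six pairs)."""
    lengths = []
    for p in pairwise_distances(rec):
        for s, e in _runs(p.d <= dist_cutoff):
            lengths.append((e - s) / p.frame_rate)
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        return np.zeros(len(durations))
    return np.array([(lengths >= d).sum() for d in durations], dtype=float)


def _welch_effective(a: np.ndarray, b: np.ndarray, n_eff: int) -> float:
    """Welch t-test with the null sample's size capped at its effective n.

    Ensemble members recombine the same source fish, so the variance of the
    ensemble mean scales with the number of independent source groups, not
    with the member count; using the raw member count would understate the
    standard error and inflate the test.
    """
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na = len(a)
    se2 = va / na + vb / n_eff
    if se2 == 0:
        return 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / n_eff) ** 2 / (n_eff - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def _compare(
    actual: np.ndarray, null: np.ndarray, labels: np.ndarray, metric: str, n_eff: int
) -> CalibrationCurve:
    """Per-bin Welch t-tests of group-level values against member-level values."""
    p_raw = np.array(
        [_welch_effective(actual[:, k], null[:, k], n_eff) for k in range(len(labels))]
    )
    p_holm = holm_adjust(p_raw)

    def _ci(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=0)
        half = 1.959963984540054 * stats.sem(x, axis=0)
        return np.column_stack([m - half, m + half])

    curve = CalibrationCurve(
        metric=metric,
        bin_labels=labels,
        actual_mean=actual.mean(axis=0),
        actual_ci=_ci(actual),
        null_mean=null.mean(axis=0),
        null_ci=_ci(null),
        p_raw=p_raw,
        p_holm=p_holm,
    )
    if curve.significant.any():
        rule = "second_longest" if metric == "distance" else "second_shortest"
        curve.selected_cutoff = select_cutoff(curve, rule)
    return curve


def distance_calibration(
    actual: list[GroupRecording],
    null: NullEnsemble,
    candidate_cutoffs: np.ndarray | None = None,
) -> CalibrationCurve:
    """Compare actual vs null inter-fish distance histograms per 1-cm bin.

    Each candidate cutoff c tests the relative frequency of distances in
    [c-1, c) cm, per group (actual) and per member (null); frequencies over
    the full 0-56 cm range normalise the histograms.  Only the candidate
    window is tested, keeping the Holm family small.
    """
    if len(actual) < 2:
        raise ValueError("need at least 2 actual groups")
    labels = np.asarray(
        candidate_cutoffs if candidate_cutoffs is not None else np.arange(1, 11)
    )
    edges = np.concatenate([labels - 1.0, [labels[-1]]])
    a = np.stack([_distance_freqs(r, edges) for r in actual])
    b = np.stack([_distance_freqs(r, edges) for r in null.members])
    return _compare(a, b, labels, "distance", null.effective_n)


def duration_calibration(
    actual: list[GroupRecording],
    null: NullEnsemble,
    dist_cutoff: float = 5.0,
    durations: np.ndarray | None = None,
) -> CalibrationCurve:
    """Compare actual vs null inverse-cumulative sub-cutoff run counts.

    For each candidate duration d, the count of proximity runs (distance <=
    ``dist_cutoff``) lasting at least d seconds is computed per group and per
    null member; counts are non-increasing in d by construction.
    """
    if len(actual) < 2:
        raise ValueError("need at least 2 actual groups")
    durations = np.asarray(
        durations if durations is not None else np.arange(1.0, 16.0)
    )
    a = np.stack([_run_counts(r, dist_cutoff, durations) for r in actual])
    b = np.stack([_run_counts(r, dist_cutoff, durations) for r in null.members])
    return _compare(a, b, durations, "duration", null.effective_n)


def select_cutoff(curve: CalibrationCurve, rule: str) -> float:
    """Pick the conservative cutoff from the Holm-significant bins.

    ``second_longest`` (distances): next-to-largest significant value;
    ``second_shortest`` (durations): next-to-smallest; ``extreme``: the
    largest (distance sense).  A single significant bin is returned as-is.
    """
    sig = np.sort(curve.significant_bins)
    if sig.size == 0:
        raise ValueError("calibration failed: no Holm-significant bins")
    if sig.size == 1:
        import warnings

        warnings.warn("only one significant bin; returning it", stacklevel=2)
        return float(sig[0])
    if rule == "second_longest":
        return float(sig[-2])
    if rule == "second_shortest":
        return float(sig[1])
    if rule == "extreme":
        return float(sig[-1])
    raise ValueError(f"unknown rule {rule!r}")


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment, order of the input preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]
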
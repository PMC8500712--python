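# Methods

## The measurement problem

Four fish swim together in a 50.8 × 25.4 cm arena filmed at 20 frames/s for
6 min; a tracker emits per-frame X-Y coordinates per fish. The first minute
(release turbulence) is discarded, leaving 6,000 analysis frames. The goal
is to decide, per group, how much of the time fish spend near each other
reflects attraction rather than chance, and how strongly each fish turns in
one preferred direction.

## Trajectory repair

Tracker dropouts appear as absent rows. A missing run flanked by
observations is filled by constant-velocity straight-line interpolation —
the unique path with constant speed and heading between the flanks, which
is how "averaging velocity and swimming direction" across a gap resolves.
Gaps touching the recording edge have only one flank; there the nearest
observed position is held constant. This edge rule is our choice (any rule
needs one); it affects at most a few frames per recording at the default
1% gap rate. Frame-to-frame jumps above 20 cm are reported as warnings
(likely uncorrected identity switches) but never auto-repaired: identity
assignment is upstream's job. Frames are 0-based and bout intervals
half-open `[start, end)`.

## Nearby-interaction bouts and the passing-by correction

A bout is a maximal run of frames with pairwise distance ≤ R sustained for
at least D seconds (defaults R = 5 cm, D = 4 s; a run of k frames at rate f
lasts k/f s, so 80 frames at 20 fps is the shortest 4-s bout). Bouts are
strictly pairwise; a tight trio shows up as three overlapping pairwise
bouts. Per-fish totals sum each bout a fish participates in, without
union-of-intervals deduplication — simple, monotone in the cutoffs, and
consistent with subtracting the correction from *each* bout.

Two independent fish also linger within R by chance. Model both fish moving
at the group mean speed V with an isotropic heading difference
θ ~ U(0, π): the relative speed |Vr| = 2V sin(θ/2) has mean 4V/π. In the
rest frame of one fish, a chance pass crosses the radius-R disk along a
chord 2R sin(ω) with ω ~ U(0, π), mean 4R/π. The expected transit time is

    PbDur = E|L| / E|Vr| = (4R/π) / (4V/π) = R / V ,

computed once per group from V over the full analysis window and subtracted
from every bout (floored at zero: a 4-s bout with a 5-s PbDur contributes
nothing, never negative time). `pbdur_mc_oracle` verifies both expectations
and the ratio by direct Monte-Carlo draws of θ and ω.

Speed profiles split each fish's frames into during-bout, the 4-s windows
before and after (truncated at recording edges, never stealing during-bout
frames), and everything else; the contrast of during vs out-of-bout speed
is the deceleration readout.

Pairwise relative motion is also classified per 1-s window into
disperse / inverse pass / gather / fish-1 leads / fish-2 leads / none from
the distance change Δd and heading alignment cos φ. The category names are
descriptive; the thresholds (δ = 0.5 cm per window, alignment cos 60°) are
free parameters, not fitted quantities.

## Turning bias

Swimming direction is differenced every 5 frames (0.25 s): for successive
displacement vectors v₁, v₂, the signed turn is θ = atan2(v₁×v₂, v₁·v₂).
The printed single-argument arctangent of the quotient loses quadrant and
sign; the two-argument form is the quadrant-correct equivalent and is used
deliberately. Steps whose displacement is below ε = 1e-6 cm have no defined
heading and are excluded from the counts rather than counted as zero-angle
turns. With N1 clockwise (negative) and N2 anticlockwise (positive) steps,
the index is |log₂((N1 + ½)/(N2 + ½))|; the Haldane–Anscombe ½ keeps a
perfect one-way circler finite instead of infinite. The absolute value
makes the index reflection-invariant, so the y-axis convention (image
coordinates, y down) never matters.

## The regrouping null and cutoff calibration

The chance baseline regroups real fish: each ensemble member takes one fish
from each of four distinct source groups (uniform, no replacement within a
member; compositions may repeat across members), time-aligned by frame and
truncated to the shortest recording. No member pair ever shared an arena,
so member proximity is pure chance under identical marginal dynamics.

Calibration compares, per 1-cm distance bin (candidates 1–10 cm out of the
0–56 cm support) and per 1-s duration step (candidates 1–15 s), the actual
groups' values against the members': relative frequency of pairwise
distances for the distance curve; inverse-cumulative counts of sub-cutoff
runs lasting ≥ d for the duration curve (non-increasing in d by
construction). Bin widths of 1 cm / 1 s match the whole-unit bands the
method reports; the candidate windows keep the Holm family small. Both are
configurable.

**Test statistic.** Each bin uses a Welch t-test of the group values
(n = number of groups — the group is the experimental unit) against the
member values, with one correction: the member sample size entering the
standard error is capped at the number of source groups. Members recombine
the same fish — each fish appears in many members — so the variance of the
ensemble mean scales with the number of independent source groups, not the
member count; treating 200 members as 200 independent units understates the
SE and, in the rare-count duration bins (where all actual groups can have
zero events), produces unbounded t artifacts. On simulated non-interacting
cohorts (18 groups vs a 200-member ensemble, 20 independent repeats) the
capped test reported no Holm-significant bins in any repeat for either
calibration, while leaving the actual-vs-null separation of attracted
cohorts (which is many group-level standard deviations wide) untouched.

The cutoff is then chosen conservatively among Holm-significant bins:
second-longest significant distance, second-shortest significant duration
(a single significant bin is returned with a warning; none is a calibration
failure).

## The simulator

`simulate_group` is a correlated random walk per fish: per frame the
heading receives a kick of magnitude |N(0, σ)| with σ = (1 − persistence)
rad and a sign that is anticlockwise with probability `turn_bias`; speed is
N(base, sd) clipped to [0, base + 5·sd]. When a neighbour enters the
sensing radius (and attraction is on), the fish "engages" for at least
`min_dwell_s`: its heading rotates toward the nearest neighbour by the
attraction weight per frame and its speed is multiplied by the deceleration
factor. Engagement is followed by a refractory period (default 10 s) during
which the fish ignores neighbours — without it strong attraction locks
pairs together for the whole recording, which neither looks like fish nor
leaves out-of-bout frames to compare against. Walls reflect specularly with
a gentle inward nudge inside a 1-cm margin. Missing-ID gaps are injected
per frame at `gap_rate` (default 1%, matching a >97%-tracked recording),
with the first and last frame always observed. Everything is reproducible
from a single seed; cohorts derive per-group seeds from a master seed.

Defaults emulate the study conditions: 4 fish, 300 s at 20 fps after
trimming, 50.8 × 25.4 cm arena, ~3 cm/s swimming, 5-cm sensing radius.
What the simulator does **not** emulate: body posture and size (points,
not fish), hydrodynamics and lateral-line physics, burst-glide gait,
learning, and any mechanistic coupling between turning bias and sociality
beyond what persistent circling does to encounter geometry. Tests passing
on simulated cohorts therefore validate the *pipeline's* statistical
behaviour (type-I control, monotone parameter recovery, sign of the
deceleration effect), not any biological claim about real fish.

## Downstream statistics

Factorial comparisons fit the additive and full-interaction (generalized)
linear models, select by AIC, and report Holm-adjusted pairwise Welch
contrasts per factor (Gaussian family by default; family configurable since
the appropriate link depends on the response). The turning-bias vs
interaction relationship is OLS of the response on log(index + 0.01); the
offset admits perfectly balanced turners with index exactly 0. Repeatability
is the two-way random, absolute-agreement, single-measure intraclass
correlation (computed via pingouin), with a hand-coded variance-components
oracle in the tests; a zero-between-subject-variance matrix has no defined
ICC and is reported as NaN. Paired and rank tests (Wilcoxon signed-rank,
paired/Welch t) run as named contrast families with Holm adjustment across
each family.

## Problem sizes

The test suite and drivers use full-scale recordings (6,000 frames) where
the quantity under test depends on the study geometry — calibration type-I
(18 groups × 20 repeats vs 200-member ensembles) and the simulator sweeps —
and shorter recordings (90–120 s) for plumbing tests where duration is
irrelevant. The Monte-Carlo verification of the passing-by closed form uses
10⁵ draws, giving standard errors near 0.2% of the estimate.

## Known limitations

* The per-fish bout total double-counts frames where a fish holds two
  simultaneous bouts with different partners; whether the original analysis
  deduplicated is unspecified, and the chosen convention is documented
  above.
* PbDur assumes straight passes at a common speed; strongly curved paths or
  heterogeneous speeds make it an approximation (it remains a first-order
  chance correction, not a full null model).
* The five-way pair-motion classification has no ground truth; its
  thresholds are exposed as parameters and its outputs are descriptive.
* Calibration needs ≥ 4 source groups (to build the null) and ≥ 2 actual
  groups; with few groups the test is underpowered rather than invalid.
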
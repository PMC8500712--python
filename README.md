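# shoalscope

Trajectory-based quantification of social-like "nearby interactions" and
repetitive turning bias in small groups of fish recorded in the dark.

Standard shoaling metrics — inter-individual distance (IID, the mean of the
six pairwise distances in a 4-fish group) and nearest-neighbour distance
(NND) — often fail to separate weakly social fish from independent swimmers.
`shoalscope` implements a sharper, chance-corrected event metric and the
machinery to calibrate and validate it, aimed at researchers doing
post-tracking analysis of group recordings (e.g. idTracker output of
*Astyanax mexicanus* surface fish and cavefish):

* **Nearby-interaction bouts** — maximal runs where a pair of fish stays
  within a distance cutoff (5 cm) for at least a duration cutoff (4 s).
* **Passing-by correction** — two independent fish also spend time within
  5 cm by chance. With both fish at the group mean speed V and a uniform
  heading difference θ, the mean relative speed is E|Vr| = 4V/π; a straight
  pass through a radius-R disk at a uniform chord angle has mean length
  E|L| = 4R/π. Their ratio, **PbDur = R/V**, is subtracted from every bout,
  so only above-chance proximity time is counted.
* **Random-regrouping null** — virtual 4-fish groups assembled from fish
  that never swam together. Actual-vs-null comparisons of the distance
  histogram and of the run-duration curve, with Holm-corrected tests, yield
  the bands of significant separation from which the cutoffs are chosen
  conservatively (second-longest significant distance, second-shortest
  significant duration).
* **Turning-bias index** — signed turning angles at 0.25-s steps,
  θ = atan2(v₁×v₂, v₁·v₂); with N1 clockwise and N2 anticlockwise steps the
  index is |log₂(N1/N2)|, high for repetitive one-way circling.
* **Agent-based simulator** — correlated random walks with tunable
  attraction, deceleration on approach, turn bias, wall reflection and
  tracker-like missing-ID gaps, so every stage is testable without videos.
* **Downstream statistics** — AIC-selected (generalized) linear models,
  Holm post hoc contrasts, logarithmic-curve correlation of turning bias
  against interaction, intraclass-correlation repeatability, rank tests.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
cohorts (nine social groups, nine weakly-social "circler" groups; 5 min at
20 fps, 50.8 × 25.4 cm arena) and write tables under `results/`:

```sh
cd analysis
python 01_simulate_cohorts.py    # trajectories -> scratch/trajectories/
python 02_calibrate_cutoffs.py   # actual-vs-null calibration
python 03_detect_interactions.py # bouts, PbDur correction, speed profiles
python 04_turning_bias.py        # turning index + repeatability
python 05_group_statistics.py    # models, correlations, rank tests
```

Output of one full run:

```
significant distance bins (cm): [1, 2, 3]
selected distance cutoff: 2.0 cm
significant duration bins (s): [1.0, 2.0, 3.0, 4.0, 5.0]
selected duration cutoff: 2.0 s
circler: mean adjusted nearby duration 3.7 s/fish, mean bouts 1.3, PbDur 0.69 s
social: mean adjusted nearby duration 39.8 s/fish, mean bouts 10.0, PbDur 0.75 s
circler: speed during bouts 2.55 cm/s vs out-of-bout 2.88 cm/s
social: speed during bouts 1.64 cm/s vs out-of-bout 2.88 cm/s
circler: turning bias index 2.55 ± 0.67 (n=36)
social: turning bias index 0.09 ± 0.06 (n=36)
repeatability across sessions: ICC = 0.80, p = 0.0120 (N = 6)
nearby_duration_s: social vs circler t = -21.08, p (Holm) = 6.9e-26, effect r = 0.93
turning_bias_index: social vs circler t = 21.87, p (Holm) = 3.3e-22, effect r = 0.93
circler turning-bias vs nearby duration (log fit): adj R^2 = 0.041, F(1,34) = 2.5, p = 0.1246, slope = -3.9
circler: during vs out: W = 6, p (Holm) = 1.7e-06
social: during vs out: W = 0, p (Holm) = 5.8e-11
```

Reading this: the calibration finds significant actual-vs-null separation
only at short distances/durations (the simulated attraction acts inside a
5-cm sensing radius and pulls pairs close), and the conservative
second-most-extreme rule picks 2 cm / 2 s for these data. After subtracting
each group's PbDur, social fish accumulate an order of magnitude more
nearby-interaction time than circlers, decelerate during bouts (Wilcoxon
during-vs-out), and show near-zero turning bias, while circler fish carry a
strong, repeatable (ICC = 0.80) turning bias with a weak negative trend
against interaction time.

Library use in three lines:

```python
from shoalscope import SimulationParams, simulate_group, detect_group_bouts
rec = simulate_group(SimulationParams(attraction_strength=0.15, seed=1)).filled()
bouts = detect_group_bouts(rec)   # distance <= 5 cm for >= 4 s, per pair
```

## Layout

```
src/shoalscope/   io, kinematics, interactions, null_model, simulate, stats
analysis/         numbered study drivers (thin wrappers over the library)
tests/            unit, property and end-to-end acceptance tests
scripts/          acceptance.py
results/          tables written by the drivers
scratch/          bulky regenerable trajectory CSVs (not tracked)
```
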
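"""Simulate the two study cohorts and write their trajectory tables.

Two populations of nine 4-fish groups each, 5 min at 20 fps in a
50.8 x 25.4 cm arena:

* ``social``   — shoaling-prone fish: attraction toward the nearest
  neighbour within the 5 cm sensing radius, deceleration while engaged,
  balanced turning.
* ``circler``  — weakly social fish with strongly biased turning: per-group
  turn bias drawn to either side (no population-level left/right preference),
  faint attraction.

Trajectory CSVs go to scratch/trajectories/<population>/ (they are bulky and
regenerable); the manifest with per-group parameters goes to results/.
"""

import dataclasses
import json
from pathlib import Path

from shoalscope import SimulationParams, simulate_cohort, write_group

SEED = 42
N_GROUPS = 9
ROOT = Path(__file__).resolve().parents[1]

COHORTS = {
    "social": SimulationParams(
        attraction_strength=0.15, deceleration_factor=0.5, turn_bias=0.5, seed=None
    ),
    "circler": SimulationParams(
        attraction_strength=0.03, deceleration_factor=0.8, turn_bias=0.5, seed=None
    ),
}
# circler groups get a strong per-group bias, alternating side
CIRCLER_BIASES = [0.8, 0.2, 0.75, 0.25, 0.85, 0.15, 0.8, 0.2, 0.7]


def main() -> None:
    manifest = {"seed": SEED, "cohorts": {}}
    for k, (name, base) in enumerate(COHORTS.items()):
        out = ROOT / "scratch" / "trajectories" / name
        out.mkdir(parents=True, exist_ok=True)
        if name == "circler":
            recs = []
            for g, bias in enumerate(CIRCLER_BIASES):
                params = dataclasses.replace(base, turn_bias=bias)
                recs.extend(simulate_cohort(params, 1, seed=SEED * 100 + k * 50 + g))
                recs[-1] = dataclasses.replace(recs[-1], group_id=f"group{g + 1:02d}")
        else:
            recs = simulate_cohort(base, N_GROUPS, seed=SEED * 100 + k * 50)
        files = []
        for rec in recs:
            path = out / f"{rec.group_id}.csv"
            write_group(rec, path)
            files.append(path.name)
        manifest["cohorts"][name] = {
            "n_groups": len(recs),
            "params": {
                f.name: getattr(base, f.name)
                for f in dataclasses.fields(base)
                if f.name not in ("arena", "seed")
            },
            "files": files,
        }
        print(f"{name}: wrote {len(recs)} groups to {out}")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "cohort_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
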
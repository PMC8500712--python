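"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

from shoalscope import ArenaSpec, read_group

SEED = 42
ROOT = Path(__file__).resolve().parents[1]
TRAJ_DIR = ROOT / "scratch" / "trajectories"
RESULTS = ROOT / "results"


def load_cohort(name: str):
    """Read one cohort's trajectory CSVs, gap-filled, in group order."""
    arena = ArenaSpec()
    paths = sorted((TRAJ_DIR / name).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(
            f"no trajectories for cohort {name!r}; run 01_simulate_cohorts.py first"
        )
    return [read_group(p, arena).filled() for p in paths]
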
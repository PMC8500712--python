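"""Detect nearby-interaction bouts and summarize them per fish.

Applies the calibrated cutoffs to both cohorts: per group, compute the mean
swimming speed V, the passing-by duration PbDur = cutoff / V, detect the
pairwise proximity bouts, subtract PbDur from each bout, and accumulate
per-fish totals, counts, and speed profiles around the bouts.
"""

import json

import pandas as pd

from _common import ROOT, load_cohort
from shoalscope import (
    adjust_and_summarize,
    detect_group_bouts,
    group_mean_speed,
    passing_by_duration,
    speed_profile,
)


def main() -> None:
    cal = json.loads((ROOT / "results" / "calibration_summary.json").read_text())
    dist_cutoff = cal["distance"]["selected_cutoff_cm"] or 5.0
    dur_cutoff = cal["duration"]["selected_cutoff_s"] or 4.0
    print(f"using cutoffs: {dist_cutoff} cm, {dur_cutoff} s")

    fish_rows, bout_rows, prof_rows = [], [], []
    for pop in ("social", "circler"):
        for rec in load_cohort(pop):
            V = group_mean_speed(rec)
            pbm = passing_by_duration(V, dist_cutoff)
            bouts = detect_group_bouts(rec, dist_cutoff, dur_cutoff)
            adj, summary = adjust_and_summarize(bouts, pbm.pbdur, rec.fish_ids, V)
            for b in adj:
                bout_rows.append(
                    {"population": pop, "group_id": rec.group_id,
                     "fish_a": b.pair[0], "fish_b": b.pair[1],
                     "start_frame": b.start_frame, "end_frame": b.end_frame,
                     "raw_s": b.raw_duration, "adjusted_s": b.adjusted_duration}
                )
            for fid in rec.fish_ids:
                prof = speed_profile(rec, fid, adj)
                prof_rows.append(
                    {"population": pop, "group_id": rec.group_id, "fish_id": fid,
                     "before": prof.before, "during": prof.during,
                     "after": prof.after, "out": prof.out, "n_bouts": prof.n_bouts}
                )
                fish_rows.append(
                    {"population": pop, "group_id": rec.group_id, "fish_id": fid,
                     "nearby_duration_s": summary.total_adjusted_duration[fid],
                     "bout_count": summary.bout_count[fid],
                     "group_V_cms": V, "pbdur_s": pbm.pbdur}
                )

    out = ROOT / "results"
    fish = pd.DataFrame(fish_rows)
    fish.to_csv(out / "interaction_per_fish.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(out / "bouts.csv", index=False)
    profs = pd.DataFrame(prof_rows)
    profs.to_csv(out / "speed_profiles.csv", index=False)

    for pop, grp in fish.groupby("population"):
        print(
            f"{pop}: mean adjusted nearby duration "
            f"{grp['nearby_duration_s'].mean():.1f} s/fish, "
            f"mean bouts {grp['bout_count'].mean():.1f}, "
            f"PbDur {grp['pbdur_s'].mean():.2f} s"
        )
    during_out = profs.dropna(subset=["during"])
    for pop, grp in during_out.groupby("population"):
        print(
            f"{pop}: speed during bouts {grp['during'].mean():.2f} cm/s "
            f"vs out-of-bout {grp['out'].mean():.2f} cm/s"
        )


if __name__ == "__main__":
    main()
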
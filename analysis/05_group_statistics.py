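"""Downstream statistics over the two simulated cohorts.

Factorial comparison of nearby-interaction duration and turning bias between
the populations (AIC-selected linear model, Holm post hoc), the logarithmic
correlation between turning bias and nearby interaction within the circler
population, and a rank test of during-bout vs out-of-bout speeds.
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS
from shoalscope import compare_factorial, log_curve_fit, paired_and_rank_tests


def main() -> None:
    fish = pd.read_csv(RESULTS / "interaction_per_fish.csv")
    turning = pd.read_csv(RESULTS / "turning_bias.csv")
    df = fish.merge(turning, on=["population", "group_id", "fish_id"])
    profs = pd.read_csv(RESULTS / "speed_profiles.csv")

    report = {}

    for response in ("nearby_duration_s", "turning_bias_index"):
        res = compare_factorial(df, response, ["population"])
        c = res.contrasts[0]
        report[response] = res.to_dict()
        print(
            f"{response}: social vs circler t = {c['t']:.2f}, "
            f"p (Holm) = {c['p_holm']:.2g}, effect r = {c['r']:.2f}"
        )

    circ = df[df["population"] == "circler"]
    fit = log_curve_fit(
        circ["turning_bias_index"].to_numpy(), circ["nearby_duration_s"].to_numpy()
    )
    report["log_curve_circler"] = fit
    print(
        f"circler turning-bias vs nearby duration (log fit): "
        f"adj R^2 = {fit['adj_r2']:.3f}, F(1,{fit['df'][1]}) = {fit['F']:.1f}, "
        f"p = {fit['p']:.4f}, slope = {fit['slope']:.1f}"
    )

    paired = profs.dropna(subset=["during"])
    wil = paired_and_rank_tests(
        [
            (
                f"{pop}: during vs out",
                grp["during"].to_numpy(),
                grp["out"].to_numpy(),
            )
            for pop, grp in paired.groupby("population")
        ],
        kind="wilcoxon",
    )
    report["bout_speed_tests"] = [dict(c) for c in wil.contrasts]
    for c in wil.contrasts:
        print(f"{c['contrast']}: W = {c['stat']:.0f}, p (Holm) = {c['p_holm']:.2g}")

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    (RESULTS / "stats_report.json").write_text(
        json.dumps(report, indent=2, default=_default) + "\n"
    )


if __name__ == "__main__":
    main()
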
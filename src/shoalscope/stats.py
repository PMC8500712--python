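"""Downstream statistics and study orchestration.

Group comparisons use linear / generalized-linear models with AIC model
selection and Holm-corrected post hoc contrasts; the turning-bias vs
interaction relationship is a logarithmic-curve fit; repeatability is a
two-way absolute-agreement intraclass correlation; and :func:`run_study`
drives the whole pipeline (read, trim, gap-fill, metrics, null calibration,
bout detection, speed profiles, statistics) over a directory of trajectory
CSVs to a JSON report plus tidy CSVs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats as sps

from . import interactions as si
from . import kinematics as sk
from . import null_model as snull
from .io import ArenaSpec, read_group, trim_lead_in

__all__ = [
    "StatResult",
    "compare_factorial",
    "log_curve_fit",
    "icc_repeatability",
    "paired_and_rank_tests",
    "run_study",
]


@dataclass
class StatResult:
    """Model-selection and contrast results for one response variable."""

    response: str
    factors: list[str]
    aic: dict[str, float]
    chosen_model: str
    coefficients: dict[str, float]
    contrasts: list[dict] = field(default_factory=list)
    effect_size: float | None = None

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "factors": self.factors,
            "aic": self.aic,
            "chosen_model": self.chosen_model,
            "coefficients": self.coefficients,
            "contrasts": self.contrasts,
            "effect_size": self.effect_size,
        }


def compare_factorial(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    family: str = "gaussian",
) -> StatResult:
    """Factorial group comparison with AIC model selection.

    Fits the additive model and the full-interaction model (OLS for the
    gaussian family, GLM otherwise), keeps the one with the lower AIC, and
    reports Holm-adjusted pairwise Welch contrasts between the levels of
    each factor.
    """
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if not np.isfinite(data[response]).all():
        raise ValueError("response contains non-finite values")
    cells = data.groupby(factors, observed=True)[response].count()
    if len(factors) > 1 and (cells < 2).any():
        raise ValueError("at least one design cell has fewer than 2 observations")

    terms = " + ".join(f"C({f})" for f in factors)
    inter = " * ".join(f"C({f})" for f in factors)
    formulas = {"additive": f"{response} ~ {terms}"}
    if len(factors) > 1:
        formulas["interaction"] = f"{response} ~ {inter}"

    def _fit(formula: str):
        if family == "gaussian":
            return smf.ols(formula, data=data).fit()
        import statsmodels.api as sm

        fam = {"poisson": sm.families.Poisson(), "gamma": sm.families.Gamma()}[family]
        return smf.glm(formula, data=data, family=fam).fit()

    fits = {name: _fit(f) for name, f in formulas.items()}
    aic = {name: float(m.aic) for name, m in fits.items()}
    chosen = min(aic, key=aic.get)
    best = fits[chosen]

    contrasts = []
    p_raw = []
    for f in factors:
        levels = sorted(data[f].unique())
        for a, b in itertools.combinations(levels, 2):
            xa = data.loc[data[f] == a, response]
            xb = data.loc[data[f] == b, response]
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            # effect size r from the t statistic
            df_w = len(xa) + len(xb) - 2
            r = float(abs(t) / np.sqrt(t**2 + df_w)) if df_w > 0 else np.nan
            contrasts.append(
                {"factor": f, "levels": (str(a), str(b)), "t": float(t),
                 "p_raw": float(p), "r": r}
            )
            p_raw.append(float(p))
    p_holm = snull.holm_adjust(np.array(p_raw)) if p_raw else np.array([])
    for c, ph in zip(contrasts, p_holm):
        c["p_holm"] = float(ph)

    rsq = getattr(best, "rsquared_adj", None)
    return StatResult(
        response=response,
        factors=list(factors),
        aic=aic,
        chosen_model=chosen,
        coefficients={k: float(v) for k, v in best.params.items()},
        contrasts=contrasts,
        effect_size=float(rsq) if rsq is not None else None,
    )


def log_curve_fit(
    x: np.ndarray, y: np.ndarray, offset: float = 0.01
) -> dict:
    """OLS of y on log(x + offset): the turning-bias vs interaction curve.

    The small offset keeps zero turning-bias indices (perfectly balanced
    turners) inside the transform's domain.  Returns adjusted R², the F test
    and the two coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for the logarithmic fit")
    df = pd.DataFrame({"logx": np.log(x + offset), "y": y})
    fit = smf.ols("y ~ logx", data=df).fit()
    return {
        "adj_r2": float(fit.rsquared_adj),
        "F": float(fit.fvalue),
        "df": (int(fit.df_model), int(fit.df_resid)),
        "p": float(fit.f_pvalue),
        "intercept": float(fit.params["Intercept"]),
        "slope": float(fit.params["logx"]),
        "offset": offset,
    }


def icc_repeatability(measurements: np.ndarray) -> tuple[float, float]:
    """Repeatability of a per-fish phenotype across sessions.

    ``measurements`` is a subjects x sessions matrix.  Computes the two-way
    random, absolute-agreement, single-measure intraclass correlation (ICC2)
    with its F-test p-value.  Returns (nan, nan) when between-subject
    variance is zero, where the ICC is undefined.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 sessions")
    if np.isclose(np.var(m.mean(axis=1)), 0.0) and np.isclose(np.var(m), 0.0):
        return float("nan"), float("nan")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(m.shape[0]), m.shape[1]),
            "session": np.tile(np.arange(m.shape[1]), m.shape[0]),
            "value": m.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="session", ratings="value"
    ).set_index("Type")
    # two-way random, absolute agreement, single measures; the label differs
    # across pingouin versions
    label = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[label]
    return float(row["ICC"]), float(row["pval"])


def paired_and_rank_tests(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]],
    kind: str = "wilcoxon",
) -> StatResult:
    """Run one family of paired/two-sample tests with Holm adjustment.

    ``kind``: "wilcoxon" (signed-rank, paired), "paired_t", or "welch_t"
    (independent).  Each contrast is (name, x, y).
    """
    results = []
    p_raw = []
    for name, x, y in contrasts:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if min(len(x), len(y)) < 2:
            raise ValueError(f"contrast {name!r}: need at least 2 observations")
        if kind == "wilcoxon":
            if np.allclose(x, y):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(x, y)
        elif kind == "paired_t":
            stat, p = sps.ttest_rel(x, y)
        elif kind == "welch_t":
            stat, p = sps.ttest_ind(x, y, equal_var=False)
        else:
            raise ValueError(f"unknown test kind {kind!r}")
        results.append({"contrast": name, "stat": float(stat), "p_raw": float(p)})
        p_raw.append(float(p))
    for rec, ph in zip(results, snull.holm_adjust(np.array(p_raw))):
        rec["p_holm"] = float(ph)
    return StatResult(
        response=kind,
        factors=[r["contrast"] for r in results],
        aic={},
        chosen_model=kind,
        coefficients={},
        contrasts=results,
    )


def run_study(config: dict) -> dict:
    """Run the full pipeline over a directory of trajectory CSVs.

    Config keys (defaults in parentheses): ``data_dir``; ``out_dir``;
    ``arena`` {width, height, frame_rate, px_per_cm}; ``trim_s`` (60);
    ``null_n`` (200); ``seed`` (0); ``calibrate`` (True) or fixed
    ``dist_cutoff`` (5) / ``dur_cutoff`` (4); ``groups`` — optional mapping
    of file stem to {population, ...} labels.
    """
    data_dir = Path(config["data_dir"])
    out_dir = Path(config.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    arena_cfg = config.get("arena", {})
    arena = ArenaSpec(
        width=arena_cfg.get("width", 50.8),
        height=arena_cfg.get("height", 25.4),
        frame_rate=arena_cfg.get("frame_rate", 20.0),
        px_per_cm=arena_cfg.get("px_per_cm"),
    )
    seed = int(config.get("seed", 0))
    trim_s = float(config.get("trim_s", 60.0))
    labels = config.get("groups", {})

    paths = sorted(data_dir.glob("*.csv"))
    if not paths:
        raise ValueError(f"no trajectory CSVs found in {data_dir}")
    recs = []
    for p in paths:
        meta = labels.get(p.stem, {})
        rec = read_group(p, arena, population_label=meta.get("population", "synthetic"))
        if trim_s > 0 and trim_s * arena.frame_rate <= rec.n_frames:
            rec = trim_lead_in(rec, trim_s)
        recs.append(rec.filled())

    report: dict = {"seed": seed, "n_groups": len(recs), "trim_s": trim_s}

    # cutoffs: calibrate against a regrouping null when possible
    dist_cutoff = float(config.get("dist_cutoff", si.DIST_CUTOFF_CM))
    dur_cutoff = float(config.get("dur_cutoff", si.DUR_CUTOFF_S))
    if config.get("calibrate", True) and len(recs) >= 4:
        null = snull.build_null_groups(recs, n=int(config.get("null_n", 200)), seed=seed)
        dcal = snull.distance_calibration(recs, null)
        if dcal.selected_cutoff is not None:
            dist_cutoff = dcal.selected_cutoff
        ucal = snull.duration_calibration(recs, null, dist_cutoff=dist_cutoff)
        if ucal.selected_cutoff is not None:
            dur_cutoff = ucal.selected_cutoff
        report["calibration"] = {
            "distance": _curve_dict(dcal),
            "duration": _curve_dict(ucal),
        }
    report["dist_cutoff_cm"] = dist_cutoff
    report["dur_cutoff_s"] = dur_cutoff

    fish_rows, bout_rows, profile_rows = [], [], []
    for rec in recs:
        V = si.group_mean_speed(rec)
        pbm = si.passing_by_duration(V, dist_cutoff)
        bouts = si.detect_group_bouts(rec, dist_cutoff, dur_cutoff)
        adj, summary = si.adjust_and_summarize(bouts, pbm.pbdur, rec.fish_ids, V)
        for b in adj:
            bout_rows.append(
                {"group_id": rec.group_id, "fish_a": b.pair[0], "fish_b": b.pair[1],
                 "start_frame": b.start_frame, "end_frame": b.end_frame,
                 "raw_s": b.raw_duration, "adjusted_s": b.adjusted_duration}
            )
        for traj in rec.trajectories:
            ts = sk.turning_angles(traj)
            prof = si.speed_profile(rec, traj.fish_id, adj)
            profile_rows.append(
                {"group_id": rec.group_id, "fish_id": traj.fish_id,
                 "before": prof.before, "during": prof.during,
                 "after": prof.after, "out": prof.out}
            )
            fish_rows.append(
                {
                    "group_id": rec.group_id,
                    "fish_id": traj.fish_id,
                    "population": rec.population_label,
                    "total_distance_cm": sk.total_distance(traj),
                    "position_index": sk.position_index(traj, rec.arena),
                    "turning_bias_index": sk.turning_bias_index(ts),
                    "n1": ts.n_cw,
                    "n2": ts.n_acw,
                    "nearby_duration_s": summary.total_adjusted_duration[traj.fish_id],
                    "bout_count": summary.bout_count[traj.fish_id],
                    "mean_speed_cms": float(sk.speed_series(traj).mean()),
                    "group_V_cms": V,
                    "pbdur_s": pbm.pbdur,
                }
            )

    fish_df = pd.DataFrame(fish_rows)
    fish_df.to_csv(out_dir / "per_fish_metrics.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(out_dir / "bouts.csv", index=False)
    pd.DataFrame(profile_rows).to_csv(out_dir / "speed_profiles.csv", index=False)

    if fish_df["population"].nunique() >= 2:
        stat = compare_factorial(fish_df, "nearby_duration_s", ["population"])
        report["population_comparison"] = stat.to_dict()
    fit = log_curve_fit(
        fish_df["turning_bias_index"].to_numpy(),
        fish_df["nearby_duration_s"].to_numpy(),
    )
    report["turning_vs_interaction"] = fit

    report["per_fish_means"] = {
        k: float(fish_df[k].mean())
        for k in ["total_distance_cm", "position_index", "turning_bias_index",
                  "nearby_duration_s", "bout_count"]
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _curve_dict(curve: snull.CalibrationCurve) -> dict:
    return {
        "bins": curve.bin_labels.tolist(),
        "actual_mean": curve.actual_mean.tolist(),
        "null_mean": curve.null_mean.tolist(),
        "p_holm": curve.p_holm.tolist(),
        "significant_bins": curve.significant_bins.tolist(),
        "selected_cutoff": curve.selected_cutoff,
    }


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
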
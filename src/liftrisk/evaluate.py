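"""Accuracy metrics and statistics for simulated-workday risk estimates.

Compares trunk-only, trunk+force, and lift-counter risk estimates against
lab-based (ground truth) risk, per participant and pooled:

* RMSE of daily risk, on the 0-100 percentage scale;
* fraction of days within a +-10-point full-scale band (inclusive: a lab
  risk of 65% counts estimates from 55% to 75% as within);
* Pearson r per participant, pooled by averaging Fisher z transforms;
* a normality check (one-sample Kolmogorov-Smirnov against a normal with the
  sample mean and SD, Lilliefors-corrected p), a paired t-test between
  condition RMSEs, and Cohen's d using the pooled SD of the two conditions;
* correlations of trunk risk with lift count and mean bend angle, the two
  quantities a trunk IMU can actually observe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal

RISK_SCALE = 100.0  # risks are reported on the 0-100 percent scale


def rmse(estimates, truths) -> float:
    """Root-mean-square error between two equal-length risk vectors."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    if est.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def within_band_fraction(estimates, truths, band: float = 10.0) -> float:
    """Fraction of days with |estimate - truth| <= band (absolute points, inclusive)."""
    if band < 0:
        raise ValueError("band must be >= 0")
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    return float(np.mean(np.abs(est - tru) <= band))


def pearson_by_participant(
    results: pd.DataFrame, condition: str, truth_col: str = "risk_lab"
) -> pd.Series:
    """Pearson r between a condition's risk and lab risk, per participant.

    A participant with zero variance in either vector yields NaN with a
    warning and is excluded from any downstream Fisher pooling.
    """
    col = f"risk_{condition}"
    out = {}
    for pid, group in results.groupby("participant_id"):
        x = group[col].to_numpy()
        y = group[truth_col].to_numpy()
        if len(x) < 3:
            raise ValueError(f"participant {pid}: need >= 3 days for a correlation")
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"participant {pid}: zero variance, correlation undefined", stacklevel=2
            )
            out[pid] = np.nan
        else:
            out[pid] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name=f"r_{condition}")


def fisher_average(r_values) -> float:
    """Average correlations on the Fisher z scale: tanh(mean(atanh(r)))."""
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no finite correlations to average")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 has infinite Fisher z; cannot average")
    return float(np.tanh(np.mean(np.arctanh(r))))


def compare_conditions(rmse_a, rmse_b) -> dict:
    """Paired comparison of two per-participant RMSE vectors.

    Returns KS-normality p-values for each vector, the paired t statistic
    with its two-sided p, and Cohen's d under the pooled-SD definition
    ``(mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)``.
    """
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if a.size >= 4:  # the Lilliefors table needs >= 4 observations
        ks_a = float(kstest_normal(a, dist="norm")[1])
        ks_b = float(kstest_normal(b, dist="norm")[1])
    else:
        ks_a = ks_b = float("nan")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        warnings.warn("zero-variance paired differences; t reported as 0", stacklevel=2)
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    pooled_sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    d = 0.0 if pooled_sd == 0 else float((a.mean() - b.mean()) / pooled_sd)
    return {
        "ks_p_a": ks_a,
        "ks_p_b": ks_b,
        "ks_note": "one-sample KS vs normal(sample mean, sample SD), Lilliefors p",
        "t": t_stat,
        "p": p_val,
        "cohens_d": d,
        "cohens_d_definition": "pooled SD of the two conditions",
    }


def trunk_risk_drivers(results: pd.DataFrame) -> dict:
    """Pooled correlations of trunk risk with lift count and mean bend angle."""
    out = {}
    x = results["risk_trunk"].to_numpy()
    for key, col in (("r_vs_lift_count", "n_lifts"), ("r_vs_bend_angle", "mean_bend_angle")):
        y = results[col].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"zero variance computing {key}", stacklevel=2)
            out[key] = np.nan
        else:
            out[key] = float(stats.pearsonr(x, y).statistic)
    return out


def summarize(results: pd.DataFrame, band: float = 10.0) -> dict:
    """Full evaluation summary of a workday-simulation table.

    Risks are converted to the 0-100 scale before any error metric, so RMSE
    and the band are in absolute percentage points of risk.
    """
    per_participant: dict[str, dict] = {}
    rmse_trunk, rmse_tf, rmse_lc = [], [], []
    within_trunk, within_tf = [], []
    for pid, group in results.groupby("participant_id"):
        lab = group["risk_lab"].to_numpy() * RISK_SCALE
        trunk = group["risk_trunk"].to_numpy() * RISK_SCALE
        tf = group["risk_trunkforce"].to_numpy() * RISK_SCALE
        lc = group["risk_liftcounter"].to_numpy() * RISK_SCALE
        entry = {
            "rmse_trunk": rmse(trunk, lab),
            "rmse_trunkforce": rmse(tf, lab),
            "rmse_liftcounter": rmse(lc, lab),
            "within10_trunk": within_band_fraction(trunk, lab, band),
            "within10_trunkforce": within_band_fraction(tf, lab, band),
        }
        per_participant[str(int(pid))] = entry
        rmse_trunk.append(entry["rmse_trunk"])
        rmse_tf.append(entry["rmse_trunkforce"])
        rmse_lc.append(entry["rmse_liftcounter"])
        within_trunk.append(entry["within10_trunk"])
        within_tf.append(entry["within10_trunkforce"])

    r_trunk = pearson_by_participant(results, "trunk")
    r_tf = pearson_by_participant(results, "trunkforce")
    for pid in per_participant:
        per_participant[pid]["r_trunk"] = float(r_trunk[int(pid)])
        per_participant[pid]["r_trunkforce"] = float(r_tf[int(pid)])

    summary = {
        "per_participant": per_participant,
        "pooled": {
            "rmse_trunk_mean": float(np.mean(rmse_trunk)),
            "rmse_trunk_sd": float(np.std(rmse_trunk, ddof=1)) if len(rmse_trunk) > 1 else 0.0,
            "rmse_trunkforce_mean": float(np.mean(rmse_tf)),
            "rmse_trunkforce_sd": float(np.std(rmse_tf, ddof=1)) if len(rmse_tf) > 1 else 0.0,
            "rmse_liftcounter_mean": float(np.mean(rmse_lc)),
            "within10_trunk_mean": float(np.mean(within_trunk)),
            "within10_trunkforce_mean": float(np.mean(within_tf)),
            "r_trunk_pooled": fisher_average(r_trunk),
            "r_trunkforce_pooled": fisher_average(r_tf),
        },
        "drivers": trunk_risk_drivers(results),
        "band_pct": band,
        "risk_scale": "0-100 percent",
    }
    if len(rmse_trunk) >= 3:
        summary["tests"] = compare_conditions(rmse_trunk, rmse_tf)
    return summary
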
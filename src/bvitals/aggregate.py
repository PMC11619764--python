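"""Weekly summaries, global features and within-person deviations.

For a PHQ-8 observation in week ``t`` the weekly summary feature ``X_it``
is the mean (or SD) of a daily feature over the window running from 00:00
seven days before the PHQ-8 date up to the PHQ-8 timestamp — i.e. seven
full days plus any part of the PHQ-8 day itself.  A summary is valid only
when at least five days in the window carry the feature.  The global
feature ``X̄_i`` is the participant's mean of their valid weekly values
across the study, and the weekly deviation is ``ΔX_it = X_it − X̄_i``:
the global level indexes *who* tends to have higher symptoms, the
deviation indexes *when* a given person does.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: The 18 selected summary features: means and SDs of the sleep proxies,
#: mean number of sleep interruptions, means and SDs of step count and
#: walking rate, mean normalized location entropy, and means and SDs of the
#: log cluster count, hours at home and log distance traveled.
SUMMARY_FEATURES: tuple[tuple[str, str], ...] = (
    ("sleep_start", "mean"),
    ("sleep_start", "sd"),
    ("wake_time", "mean"),
    ("wake_time", "sd"),
    ("time_in_bed", "mean"),
    ("time_in_bed", "sd"),
    ("n_interruptions", "mean"),
    ("step_count_k", "mean"),
    ("step_count_k", "sd"),
    ("walking_rate", "mean"),
    ("walking_rate", "sd"),
    ("norm_location_entropy", "mean"),
    ("n_location_clusters_log", "mean"),
    ("n_location_clusters_log", "sd"),
    ("time_at_home", "mean"),
    ("time_at_home", "sd"),
    ("dist_traveled_log", "mean"),
    ("dist_traveled_log", "sd"),
)

MIN_VALID_DAYS = 5
CORR_FLAG_THRESHOLD = 0.70


def summary_key(feature: str, statistic: str) -> str:
    return f"{feature}|{statistic}"


def summarize_weekly(
    daily: pd.DataFrame,
    phq: pd.DataFrame,
    features: tuple[tuple[str, str], ...] = SUMMARY_FEATURES,
    min_valid_days: int = MIN_VALID_DAYS,
) -> pd.DataFrame:
    """Weekly summary features for every participant-wave.

    ``daily`` has one row per participant-day with feature columns (NaN =
    unavailable that day); ``phq`` has participant_id, week and timestamp.
    A day contributes to a given feature's summary only if that feature is
    non-missing on that day, so ``n_valid_days`` is feature-specific.
    Weekly SDs use the n−1 denominator.  Values of invalid summaries
    (fewer than ``min_valid_days`` contributing days) are reported as NaN.
    """
    feat_cols = sorted({f for f, _ in features})
    merged = daily[["participant_id", "date", *feat_cols]].merge(
        phq[["participant_id", "week", "timestamp"]], on="participant_id", how="inner"
    )
    ts = pd.to_datetime(merged["timestamp"])
    date = pd.to_datetime(merged["date"])
    lo = ts.dt.normalize() - pd.Timedelta(days=7)
    in_window = (date >= lo) & (date < ts)
    merged = merged[in_window]

    parts = []
    if len(merged):
        agg = merged.groupby(["participant_id", "week"])[feat_cols].agg(
            ["mean", "std", "count"]
        )
        pid_idx = agg.index.get_level_values(0)
        week_idx = agg.index.get_level_values(1).astype(int)
        for feature, stat in features:
            n = agg[(feature, "count")].to_numpy()
            valid = n >= min_valid_days
            val = agg[(feature, "mean" if stat == "mean" else "std")].to_numpy(dtype=float)
            val = np.where(valid, val, np.nan)
            parts.append(
                pd.DataFrame(
                    {
                        "participant_id": pid_idx,
                        "week": week_idx,
                        "feature": feature,
                        "statistic": stat,
                        "value": val,
                        "n_valid_days": n.astype(int),
                        "valid": valid,
                    }
                )
            )
    out = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(
            columns=[
                "participant_id", "week", "feature", "statistic",
                "value", "n_valid_days", "valid",
            ]
        )
    )
    # waves whose window holds no daily record drop out of the groupby;
    # restore them as invalid summaries so the audit sees every wave
    expected = phq[["participant_id", "week"]].drop_duplicates().merge(
        pd.DataFrame(features, columns=["feature", "statistic"]), how="cross"
    )
    out = expected.merge(
        out, on=["participant_id", "week", "feature", "statistic"], how="left"
    )
    out["n_valid_days"] = out["n_valid_days"].fillna(0).astype(int)
    out["valid"] = out["valid"].fillna(False).astype(bool)
    return out.sort_values(
        ["participant_id", "week", "feature", "statistic"], kind="stable"
    ).reset_index(drop=True)


def compute_globals(weekly: pd.DataFrame) -> pd.DataFrame:
    """Global feature per participant: unweighted mean over valid weeks.

    Participants with zero valid weeks for a feature are absent from the
    result for that feature (and hence excluded from that feature's model).
    """
    valid = weekly[weekly["valid"]]
    g = (
        valid.groupby(["participant_id", "feature", "statistic"])["value"]
        .agg(value="mean", n_valid_weeks="count")
        .reset_index()
    )
    return g


def compute_deviations(weekly: pd.DataFrame, globals_: pd.DataFrame) -> pd.DataFrame:
    """Feature triples (X_it, X̄_i, ΔX_it) for every valid participant-wave."""
    valid = weekly[weekly["valid"]][
        ["participant_id", "week", "feature", "statistic", "value"]
    ].rename(columns={"value": "x_weekly"})
    gl = globals_.rename(columns={"value": "x_global"})[
        ["participant_id", "feature", "statistic", "x_global"]
    ]
    tri = valid.merge(gl, on=["participant_id", "feature", "statistic"], how="inner")
    tri["x_dev"] = tri["x_weekly"] - tri["x_global"]
    return tri.sort_values(
        ["participant_id", "week", "feature", "statistic"], kind="stable"
    ).reset_index(drop=True)


def aggregate(daily: pd.DataFrame, phq: pd.DataFrame, **kw):
    """Convenience wrapper: weekly summaries, globals and triples in one go."""
    weekly = summarize_weekly(daily, phq, **kw)
    globals_ = compute_globals(weekly)
    triples = compute_deviations(weekly, globals_)
    return weekly, globals_, triples


def screen_correlations(
    globals_: pd.DataFrame, threshold: float = CORR_FLAG_THRESHOLD, min_pairs: int = 3
):
    """Spearman correlation screen over the global features.

    Returns the full rank-correlation matrix (summaries × summaries),
    a dict of distribution summaries of the off-diagonal |r| values, and a
    DataFrame of flagged pairs with |r| ≥ ``threshold``.  Pairs with fewer
    than ``min_pairs`` complete observations (or a constant feature) are
    reported as missing.
    """
    wide = globals_.assign(
        summary=[summary_key(f, s) for f, s in zip(globals_["feature"], globals_["statistic"])]
    ).pivot_table(index="participant_id", columns="summary", values="value")
    corr = wide.corr(method="spearman", min_periods=min_pairs)
    # constant columns give undefined correlations
    nunique = wide.nunique(dropna=True)
    for col in corr.columns:
        if nunique.get(col, 0) <= 1:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, 1.0)

    cols = list(corr.columns)
    vals, flagged = [], []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r):
                vals.append(abs(r))
                if abs(r) >= threshold:
                    flagged.append({"feature_a": a, "feature_b": b, "r": float(r)})
    vals = np.array(vals)
    summary = {
        "n_pairs": int(len(vals)),
        "median_abs_r": float(np.median(vals)) if len(vals) else np.nan,
        "q1_abs_r": float(np.percentile(vals, 25)) if len(vals) else np.nan,
        "q3_abs_r": float(np.percentile(vals, 75)) if len(vals) else np.nan,
        "n_flagged": len(flagged),
    }
    flagged_df = pd.DataFrame(flagged, columns=["feature_a", "feature_b", "r"])
    return corr, summary, flagged_df


def spearman(x, y) -> float:
    """Spearman rank correlation of two sequences (complete pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    return float(sps.spearmanr(x[ok], y[ok]).statistic)


def audit_missingness(
    weekly: pd.DataFrame,
    phq: pd.DataFrame,
    daily: pd.DataFrame | None = None,
    n_possible_waves: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant and cohort-level missing-data audit.

    Counts observed PHQ-8 waves and valid weekly summaries per feature for
    every participant (participants present in the daily table but with no
    observed waves appear with count 0), plus each participant's median
    daily overall coverage when a daily table is given.
    """
    pids = set(phq["participant_id"])
    if daily is not None and len(daily):
        pids |= set(daily["participant_id"])
    if len(weekly):
        pids |= set(weekly["participant_id"])
    pids = sorted(pids)

    phq_counts = phq.groupby("participant_id")["week"].count()
    valid_weeks = (
        weekly[weekly["valid"]]
        .groupby(["participant_id", "feature", "statistic"])["week"]
        .count()
        .groupby("participant_id")
        .mean()
        if len(weekly)
        else pd.Series(dtype=float)
    )
    rows = []
    for pid in pids:
        row = {
            "participant_id": pid,
            "n_phq_observed": int(phq_counts.get(pid, 0)),
            "mean_valid_weeks_per_feature": float(valid_weeks.get(pid, 0.0)),
        }
        if daily is not None and len(daily):
            cov = daily.loc[daily["participant_id"] == pid, "coverage_overall"]
            row["median_daily_coverage"] = float(cov.median()) if len(cov) else np.nan
        rows.append(row)
    per = pd.DataFrame(rows)
    cohort = {
        "n_participants": len(pids),
        "n_possible_waves": n_possible_waves,
        "mean_phq_observed": float(per["n_phq_observed"].mean()) if len(per) else np.nan,
        "sd_phq_observed": float(per["n_phq_observed"].std(ddof=1)) if len(per) > 1 else np.nan,
        "mean_valid_weeks_per_feature": float(per["mean_valid_weeks_per_feature"].mean())
        if len(per)
        else np.nan,
    }
    if daily is not None and len(daily) and "median_daily_coverage" in per:
        cohort["median_daily_coverage"] = float(per["median_daily_coverage"].median())
    return per, cohort
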
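"""Synthetic passive-sensing cohort generator.

The generator works top-down through three layers that mirror how the real
data arise:

1. **Person-level traits** — demographics plus latent behavioral set
   points (typical wake time and its day-to-day variability, typical
   bedtime, daily steps, walking rate, number of location clusters, home
   dwell fraction, distances from home).
2. **Daily true features** — each day's behavioral feature drawn around
   the person's set point with their own day-to-day spread, together with
   the day's location dwell profile and per-stream coverage.
3. **Event streams** — location visits, pedometer bouts, activity bouts
   and display on/off intervals laid out so that the extraction module
   recovers the daily features (steps exactly, sleep times to the minute,
   dwell-derived features to float precision): the round-trip contract.

PHQ-8 outcomes are drawn from the same between/within mixed model the
analysis fits: PHQ_it = β0 + Σ_f (βB,f·X̄_if + βW,f·ΔX_itf) + γ·c_it +
b0_i + b1_i·√t + ε_it, rounded and clamped to the 0–24 range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .aggregate import aggregate, summary_key, SUMMARY_FEATURES
from .config import SimulationConfig, ConfigError

COVARIATE_COLS = ("age", "female", "employed", "alone", "treatment")

# waking-day display alternation (hours); on-blocks stay longer than the
# sleep detector's 20-min bridging limit so daytime gaps never chain
_ON_LO, _ON_HI = 0.45, 0.9
_OFF_LO, _OFF_HI = 0.15, 0.30
_INTERRUPTION_H = 5.0 / 60.0


class GenerationError(RuntimeError):
    """Raised when a requested daily record cannot be rendered."""


def _rng(seed, *tags) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, tags)])


def _tnorm(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draw via inverse-CDF; degenerates to the clipped
    mean wherever sd = 0."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    pos = sd > 0
    safe_sd = np.where(pos, sd, 1.0)
    fa = ndtr((lo - mean) / safe_sd)
    fb = ndtr((hi - mean) / safe_sd)
    u = rng.uniform(fa, fb, size=size)
    x = np.clip(mean + safe_sd * ndtri(u), lo, hi)
    return np.where(pos, x, np.clip(mean, lo, hi)) if size is not None else (
        x if bool(np.all(pos)) else np.clip(mean, lo, hi)
    )


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw person-level traits for the whole cohort (one row per person)."""
    config.validate()
    n = config.n_participants
    td = config.trait_distributions
    rng = _rng(config.seed, 1)
    if n == 0:
        return pd.DataFrame()

    def t(name):
        return td[name]

    traits = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    traits["age"] = np.round(
        _tnorm(rng, t("age")["mean"], t("age")["sd"], t("age")["lo"], t("age")["hi"], n), 1
    )
    traits["female"] = (rng.random(n) < t("female_prob")["p"]).astype(int)
    traits["employed"] = (rng.random(n) < t("employed_prob")["p"]).astype(int)
    traits["alone"] = (rng.random(n) < t("alone_prob")["p"]).astype(int)
    traits["treatment"] = (rng.random(n) < t("treatment_prob")["p"]).astype(int)

    d = t("wake_mu")
    traits["wake_mu"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("wake_sd")
    traits["wake_sd"] = np.clip(
        rng.lognormal(d["log_mean"], d["log_sd"], n), d["lo"], d["hi"]
    )
    d = t("sleep_start_mu")
    traits["sleep_start_mu"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("sleep_start_sd")
    traits["sleep_start_sd"] = np.clip(
        rng.lognormal(d["log_mean"], d["log_sd"], n), d["lo"], d["hi"]
    )
    d = t("interruption_rate")
    traits["interruption_rate"] = rng.gamma(d["shape"], d["scale"], n)
    d = t("steps_mu")
    traits["steps_mu"] = np.clip(rng.lognormal(d["log_mean"], d["log_sd"], n), d["lo"], d["hi"])
    d = t("steps_cv")
    traits["steps_cv"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("walk_rate_mu")
    traits["walk_rate_mu"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("away_clusters_mu")
    traits["away_clusters_mu"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("home_frac_mu")
    traits["home_frac_mu"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("away_evenness")
    traits["away_evenness"] = _tnorm(rng, d["mean"], d["sd"], d["lo"], d["hi"], n)
    d = t("dist_med")
    traits["dist_med"] = rng.lognormal(d["log_mean"], d["log_sd"], n)
    return traits


def _daily_cohort(
    traits: pd.DataFrame,
    n_days: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    include_profiles: bool,
) -> pd.DataFrame:
    """Vectorized daily-feature generation for a block of participants.

    All draws are (participants x days) matrices.  The location dwell
    profile (home + away cluster hours and distances) is simulated first;
    entropy, cluster count, time at home and distance traveled are
    deterministic functions of it, which keeps jointly infeasible feature
    combinations impossible by construction.
    """
    td = cfg.trait_distributions
    P, nd = len(traits), n_days
    shape = (P, nd)

    def col(name):
        return traits[name].to_numpy(dtype=float)[:, None]

    # sleep timing: bedtime on the since-previous-midnight axis
    sstart = _tnorm(rng, col("sleep_start_mu"), col("sleep_start_sd"), 19.5, 27.5, shape)
    wake = _tnorm(rng, col("wake_mu"), col("wake_sd"), 4.0, 13.5, shape)
    wake = np.maximum(wake, sstart - 24.0 + 3.5)  # keep the rest window >= 3.5 h
    tib = wake + 24.0 - sstart

    # per-stream daily coverage
    a, b = cfg.coverage_beta
    cov = {s: rng.beta(a, b, shape) for s in ("location", "pedometer", "activity", "display")}

    # interruptions, capped so they always fit in the rendered night
    hole = (1.0 - cov["display"]) * 24.0
    room = tib - hole - 1.2
    n_int_max = np.maximum(0, np.floor(room / 0.25)).astype(int)
    n_int = np.minimum(rng.poisson(col("interruption_rate"), shape), np.minimum(n_int_max, 6))

    # activity; steps capped so walking bouts fit between wake and 23:00
    steps = np.maximum(rng.normal(col("steps_mu"), col("steps_mu") * col("steps_cv"), shape), 100.0)
    rate = _tnorm(rng, col("walk_rate_mu"), td["walk_rate_day_sd"]["value"], 0.5, 3.0, shape)
    span = 23.0 - (wake + 0.5)
    steps = np.minimum(steps, rate * 3600.0 * 0.85 * span)
    steps = np.round(steps).astype(int)

    # location dwell profile
    max_away = 8
    k_away = np.minimum(rng.poisson(col("away_clusters_mu"), shape), max_away)
    located = cov["location"] * 24.0
    home_frac = _tnorm(rng, col("home_frac_mu"), td["home_frac_day_sd"]["value"], 0.35, 0.98, shape)
    home_frac = np.where(k_away == 0, 1.0, home_frac)
    home_h = home_frac * located

    gam = rng.gamma(np.maximum(col("away_evenness"), 1e-6)[..., None], 1.0, size=(P, nd, max_away))
    mask = np.arange(max_away)[None, None, :] < k_away[..., None]
    gam = np.where(mask, gam, 0.0)
    gsum = gam.sum(axis=2)
    q = np.divide(gam, gsum[..., None], out=np.zeros_like(gam), where=gsum[..., None] > 0)
    away_h = (located - home_h)[..., None] * q

    dists = rng.lognormal(
        np.log(col("dist_med"))[..., None], td["dist_day_log_sd"]["value"], (P, nd, max_away)
    )
    dists = np.where(mask, dists, 0.0)

    # entropy over all visited clusters (home + away)
    p_home = home_h / located
    p_away = away_h / located[..., None]
    k_total = 1 + k_away
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p_away > 0, p_away * np.log(p_away), 0.0).sum(axis=2)
        plogp += np.where(p_home > 0, p_home * np.log(p_home), 0.0)
        entropy = np.where(k_total > 1, -plogp / np.log(np.maximum(k_total, 2)), 0.0)
    entropy = np.clip(entropy, 0.0, 1.0)

    dist_mean = (q * dists).sum(axis=2)
    dist_log = np.log1p(np.where(k_away > 0, dist_mean, 0.0))

    start = pd.Timestamp(cfg.start_date)
    pid = np.repeat(traits["participant_id"].to_numpy(), nd)
    day_idx = np.tile(np.arange(nd), P)
    out = pd.DataFrame(
        {
            "participant_id": pid,
            "date": start + pd.to_timedelta(day_idx, unit="D"),
            "day_index": day_idx,
            "sleep_start": sstart.ravel(),
            "wake_time": wake.ravel(),
            "time_in_bed": tib.ravel(),
            "n_interruptions": n_int.ravel().astype(float),
            "step_count_k": steps.ravel() / 1000.0,
            "walking_rate": rate.ravel(),
            "norm_location_entropy": entropy.ravel(),
            "n_location_clusters_log": np.log1p(k_total).ravel(),
            "time_at_home": home_h.ravel(),
            "dist_traveled_log": dist_log.ravel(),
            "coverage_location": cov["location"].ravel(),
            "coverage_pedometer": cov["pedometer"].ravel(),
            "coverage_activity": cov["activity"].ravel(),
            "coverage_display": cov["display"].ravel(),
        }
    )
    out["coverage_overall"] = (
        cov["location"] + cov["pedometer"] + cov["activity"] + cov["display"]
    ).ravel() / 4.0
    out["valid_day"] = True
    if include_profiles:
        ka = k_away.ravel()
        ah = away_h.reshape(P * nd, max_away)
        dm = dists.reshape(P * nd, max_away)
        out["loc_away_h"] = [list(ah[i, : ka[i]]) for i in range(P * nd)]
        out["loc_away_dist"] = [list(dm[i, : ka[i]]) for i in range(P * nd)]
    return out


def simulate_daily_features(
    traits: pd.Series | dict,
    n_days: int,
    seed: int,
    config: SimulationConfig | None = None,
    include_profiles: bool = True,
) -> pd.DataFrame:
    """One participant's true daily features for ``n_days`` days.

    Each daily feature is drawn around the participant's latent set point
    with their own day-to-day spread; domain bounds (entropy in [0, 1],
    non-negative steps, time in bed within the clock) hold by
    construction.  Deterministic for a fixed (seed, participant) pair.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    cfg = config or SimulationConfig()
    tr = pd.DataFrame([dict(traits)])
    rng = _rng(seed, 2, int(tr["participant_id"].iloc[0]))
    return _daily_cohort(tr, n_days, rng, cfg, include_profiles)


def _alternate_waking(rng, t0: float, t1: float, segs: list) -> None:
    """Fill [t0, t1) with on/off display blocks; the block touching t1 is
    always an on-block of >= 27 min so it cannot be bridged into the night."""
    t = t0
    first = True
    while t < t1 - 0.5:
        on_len = rng.uniform(_ON_LO, _ON_HI)
        end = min(t + on_len, t1)
        segs.append((True, t, end))
        t = end
        first = False
        off_len = rng.uniform(_OFF_LO, _OFF_HI)
        if t + off_len > t1 - 0.45:
            break
        segs.append((False, t, t + off_len))
        t += off_len
    if t < t1:
        segs.append((True, t, t1))
    elif first and t1 > t0:
        segs.append((True, t0, t1))


def _complement(occupied: list[tuple[float, float]], lo: float, hi: float):
    """Sorted gaps of [lo, hi) not covered by the occupied intervals."""
    out = []
    cur = lo
    for s, e in sorted(occupied):
        s, e = max(s, lo), min(e, hi)
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return [(s, e) for s, e in out if e - s > 1e-9]


def render_event_streams(
    daily: pd.DataFrame, seed: int, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Render one participant's daily records into four event streams.

    ``daily`` holds one or more consecutive days for a single participant
    (with the ``loc_away_*`` profile columns).  Display events for a day's
    night begin on the previous evening; for the first record a synthetic
    previous evening is rendered so that single-day round trips work.
    Events are split at midnight so every event lies within one day.
    """
    if daily["participant_id"].nunique() != 1:
        raise GenerationError("render_event_streams expects a single participant")
    if "loc_away_h" not in daily.columns:
        raise GenerationError("daily records lack location profiles (include_profiles=False?)")
    daily = daily.sort_values("date").reset_index(drop=True)
    if (daily["time_in_bed"] >= 24.0).any():
        raise GenerationError("time_in_bed must be < 24 h")
    pid = int(daily["participant_id"].iloc[0])
    rng = _rng(seed, 3, pid)
    day0 = pd.Timestamp(daily["date"].iloc[0]).normalize()
    nd = len(daily)

    sstart = daily["sleep_start"].to_numpy()
    wake = daily["wake_time"].to_numpy()
    n_int = daily["n_interruptions"].to_numpy().astype(int)
    cov_disp = daily["coverage_display"].to_numpy()
    cov_ped = daily["coverage_pedometer"].to_numpy()
    cov_act = daily["coverage_activity"].to_numpy()
    steps_k = daily["step_count_k"].to_numpy()
    rate = daily["walking_rate"].to_numpy()
    home_h = daily["time_at_home"].to_numpy()
    located = daily["coverage_location"].to_numpy() * 24.0

    # ---- display: one absolute timeline in hours since midnight of day 0
    A = (np.arange(nd) - 1) * 24.0 + sstart        # night onsets
    B = np.arange(nd) * 24.0 + wake                # night ends
    A_last = (nd - 1) * 24.0 + sstart[-1] + 24.0   # final evening bedtime
    segs: list[tuple[bool, float, float]] = [(True, A[0] - 1.0, A[0])]
    for j in range(nd):
        night_lo, night_hi = A[j], B[j]
        hole_len = min((1.0 - cov_disp[j]) * 24.0, max(night_hi - night_lo - 1.0, 0.0))
        hs = max(night_lo, 24.0 * j) + 0.02
        he = hs + hole_len
        # interruptions sit after the coverage hole, away from the edges
        ilo, ihi = he + 0.3, night_hi - 0.3
        m = n_int[j] if ihi - ilo >= n_int[j] * (_INTERRUPTION_H + 0.05) else 0
        pos = (
            ilo + (ihi - ilo) * (np.arange(1, m + 1) / (m + 1.0)) if m else np.array([])
        )
        off_cursor = night_lo
        for p in sorted(np.concatenate([[hs], pos])) if hole_len > 0 else sorted(pos):
            if p == hs and hole_len > 0:
                segs.append((False, off_cursor, hs))
                off_cursor = he  # uncovered: no event emitted
            else:
                segs.append((False, off_cursor, p))
                segs.append((True, p, p + _INTERRUPTION_H))
                off_cursor = p + _INTERRUPTION_H
        segs.append((False, off_cursor, night_hi))
        next_a = A[j + 1] if j + 1 < nd else A_last
        _alternate_waking(rng, night_hi, min(next_a, nd * 24.0), segs)
    display_rows = [
        (on, s, e) for on, s, e in segs if e > s + 1e-9
    ]

    rows = {k: [] for k in ("stream", "start_h", "end_h", "cluster_id", "dist_home_m",
                            "steps", "cadence_steps_per_s", "display_on", "bout")}

    def emit(stream, s, e, cluster=np.nan, dist=np.nan, steps=np.nan, cad=np.nan,
             on=None, bout=None):
        # split at midnight boundaries so events lie within one day
        while s < e - 1e-9:
            cut = min(e, (np.floor(s / 24.0) + 1.0) * 24.0)
            rows["stream"].append(stream)
            rows["start_h"].append(s)
            rows["end_h"].append(cut)
            rows["cluster_id"].append(cluster)
            rows["dist_home_m"].append(dist)
            # payload counts (steps) go to the first fragment only
            rows["steps"].append(steps)
            rows["cadence_steps_per_s"].append(cad)
            rows["display_on"].append(on)
            rows["bout"].append(bout)
            steps = 0.0 if not np.isnan(steps) else steps
            s = cut

    for on, s, e in display_rows:
        emit("display", s, e, on=on)

    # ---- per-day location, pedometer and activity streams
    for j in range(nd):
        base = 24.0 * j
        row = daily.iloc[j]
        away_h = np.asarray(row["loc_away_h"], dtype=float)
        away_d = np.asarray(row["loc_away_dist"], dtype=float)
        gap = 24.0 - located[j]
        home1 = min(home_h[j], 6.0)
        t = base
        emit("location", t, t + home1, cluster=0, dist=0.0)
        t += home1 + gap
        for k in range(len(away_h)):
            if away_h[k] <= 1e-9:
                continue
            emit("location", t, t + away_h[k], cluster=k + 1, dist=away_d[k])
            t += away_h[k]
        if home_h[j] - home1 > 1e-9:
            emit("location", t, base + 24.0, cluster=0, dist=0.0)

        # walking bouts: equal slots between wake+0.5 and 23:00
        steps_j = int(round(steps_k[j] * 1000.0))
        T = steps_j / rate[j] / 3600.0
        span_lo, span_hi = wake[j] + 0.5, 23.0
        n_b = int(rng.integers(3, 9))
        w = (span_hi - span_lo) / n_b
        dur = np.full(n_b, T / n_b)
        jit = rng.uniform(-1.0, 1.0, n_b)
        jit -= jit.mean()
        amp = min(0.3 * dur[0], max((w - 0.05 - dur[0]) / 2.0, 0.0))
        dur = dur + jit * amp
        if (dur <= 0).any() or (dur >= w - 0.02).any():
            dur = np.full(n_b, T / n_b)
        # integer steps per bout via largest remainders
        frac = dur / dur.sum() * steps_j
        sb = np.floor(frac).astype(int)
        rem = steps_j - sb.sum()
        order = np.argsort(-(frac - sb))
        sb[order[:rem]] += 1
        bouts = []
        for i in range(n_b):
            s = base + span_lo + i * w
            e = s + dur[i]
            bouts.append((s, e))
            cad = sb[i] / (dur[i] * 3600.0) if dur[i] > 0 else 0.0
            emit("pedometer", s, e, steps=float(sb[i]), cad=cad)
            emit("activity", s, e, bout="walking")
        # zero-step / stationary filler with the coverage hole carved out
        for stream, cov_j, lab in (("pedometer", cov_ped[j], None), ("activity", cov_act[j], "stationary")):
            hole = (1.0 - cov_j) * 24.0
            occupied = list(bouts) + [(base + 0.05, base + 0.05 + hole)]
            for s, e in _complement(occupied, base, base + 24.0):
                if stream == "pedometer":
                    emit("pedometer", s, e, steps=0.0, cad=0.0)
                else:
                    emit("activity", s, e, bout=lab)

    ev = pd.DataFrame(rows)
    ev.insert(0, "participant_id", pid)
    ev["start"] = day0 + pd.to_timedelta(ev.pop("start_h"), unit="h")
    ev["end"] = day0 + pd.to_timedelta(ev.pop("end_h"), unit="h")
    return ev.sort_values(["stream", "start"], kind="stable").reset_index(drop=True)


def apply_day_missingness(
    events: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Remove whole participant-days of events, each independently with
    probability ``day_missing_prob`` (seed-deterministic)."""
    p = config.day_missing_prob
    if p <= 0 or len(events) == 0:
        return events.copy()
    rng = _rng(config.seed if seed is None else seed, 4)
    day = events["start"].dt.normalize()
    keys = pd.DataFrame({"participant_id": events["participant_id"], "day": day})
    uniq = keys.drop_duplicates().sort_values(["participant_id", "day"]).reset_index(drop=True)
    drop = uniq[rng.random(len(uniq)) < p]
    merged = keys.merge(drop.assign(_drop=True), on=["participant_id", "day"], how="left")
    return events[merged["_drop"].isna().to_numpy()].reset_index(drop=True)


def drop_days(daily: pd.DataFrame, config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Day-level missingness on a daily-feature table (same Bernoulli rule)."""
    p = config.day_missing_prob
    if p <= 0 or len(daily) == 0:
        return daily.copy()
    rng = _rng(config.seed if seed is None else seed, 4)
    uniq = daily[["participant_id", "date"]].drop_duplicates().sort_values(
        ["participant_id", "date"]
    )
    keep_mask = rng.random(len(uniq)) >= p
    keep = uniq[keep_mask]
    return daily.merge(keep, on=["participant_id", "date"], how="inner").reset_index(drop=True)


def simulate_phq(
    traits: pd.DataFrame,
    feature_triples: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw PHQ-8 observations from the between/within generating model.

    Waves are first thinned with ``wave_missing_prob``; a feature named in
    the effect map must then have a triple for every retained wave, or a
    GenerationError is raised.  Continuous scores are rounded to integers
    and clamped to [0, 24].
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 5)
    waves = list(config.phq_waves)
    n = len(traits)
    start = pd.Timestamp(config.start_date)

    idx = pd.MultiIndex.from_product(
        [traits["participant_id"], waves], names=["participant_id", "week"]
    )
    obs = pd.DataFrame(index=idx).reset_index()
    obs = obs[rng.random(len(obs)) >= config.wave_missing_prob].reset_index(drop=True)

    cov = np.asarray(config.random_effect_cov, dtype=float)
    b = rng.multivariate_normal(np.zeros(2), cov, size=n, method="svd")
    bmap = pd.DataFrame(
        {"participant_id": traits["participant_id"], "b0": b[:, 0], "b1": b[:, 1]}
    )
    obs = obs.merge(bmap, on="participant_id").merge(
        traits[["participant_id", *COVARIATE_COLS]], on="participant_id"
    )
    obs["sqrt_week"] = np.sqrt(obs["week"].astype(float))
    obs["treat_sqrt_week"] = obs["treatment"] * obs["sqrt_week"]

    lin = np.full(len(obs), float(config.intercept))
    for name, g in config.covariate_effects.items():
        lin += g * obs[name].to_numpy(dtype=float)

    if config.effect_map:
        tri = feature_triples.assign(
            summary=[
                summary_key(f, s)
                for f, s in zip(feature_triples["feature"], feature_triples["statistic"])
            ]
        )
        for key, (beta_b, beta_w) in config.effect_map.items():
            sub = tri[tri["summary"] == key][
                ["participant_id", "week", "x_global", "x_dev"]
            ]
            m = obs.merge(sub, on=["participant_id", "week"], how="left")
            if m["x_dev"].isna().any():
                missing = m[m["x_dev"].isna()][["participant_id", "week"]].iloc[0]
                raise GenerationError(
                    f"no feature triple for {key} at participant "
                    f"{missing['participant_id']} week {missing['week']}"
                )
            lin += beta_b * m["x_global"].to_numpy() + beta_w * m["x_dev"].to_numpy()

    lin += obs["b0"].to_numpy() + obs["b1"].to_numpy() * obs["sqrt_week"].to_numpy()
    if config.residual_sd > 0:
        lin = lin + rng.normal(0.0, config.residual_sd, len(obs))
    phq8 = np.clip(np.round(lin), 0, 24).astype(int)

    out = obs[["participant_id", "week"]].copy()
    out["timestamp"] = (
        start
        + pd.to_timedelta(out["week"] * 7, unit="D")
        + pd.to_timedelta(config.phq_hour, unit="h")
    )
    out["phq8"] = phq8
    return out


@dataclass
class SimulatedStudy:
    """A fully simulated study: inputs, intermediates and ground truth."""

    config: SimulationConfig
    traits: pd.DataFrame
    daily_true: pd.DataFrame
    daily_observed: pd.DataFrame
    phq: pd.DataFrame
    weekly: pd.DataFrame
    globals_: pd.DataFrame
    triples: pd.DataFrame
    truth: dict


def simulate_dataset(
    config: SimulationConfig,
    include_profiles: bool = True,
    features: tuple[tuple[str, str], ...] = SUMMARY_FEATURES,
) -> SimulatedStudy:
    """Simulate the whole study at the daily-feature level.

    True daily features are complete; generation-side weekly summaries,
    globals and deviations are computed from them (a participant's symptoms
    do not depend on whether their phone was observed), PHQ-8 is drawn from
    the mixed model, and missingness is applied afterwards to the observed
    copies.  Event streams are rendered separately (see
    :func:`render_cohort_events`) when raw-stream inputs are needed.
    """
    config.validate()
    traits = simulate_cohort(config)
    n_days = config.n_weeks * 7 + 1
    if len(traits):
        rng = _rng(config.seed, 2)
        daily_true = _daily_cohort(traits, n_days, rng, config, include_profiles)
    else:
        daily_true = pd.DataFrame()

    # PHQ schedule (complete) for generation-side windows
    phq_full = pd.DataFrame(
        [
            {"participant_id": pid, "week": t}
            for pid in traits.get("participant_id", [])
            for t in config.phq_waves
        ]
    )
    if len(phq_full):
        phq_full["timestamp"] = (
            pd.Timestamp(config.start_date)
            + pd.to_timedelta(phq_full["week"] * 7, unit="D")
            + pd.to_timedelta(config.phq_hour, unit="h")
        )
        plain = daily_true.drop(columns=["loc_away_h", "loc_away_dist"], errors="ignore")
        # the effect-map features must be aggregated even if not requested
        needed = [tuple(k.split("|")) for k in config.effect_map]
        feats = tuple(dict.fromkeys([*features, *needed]))
        weekly, globals_, triples = aggregate(plain, phq_full, features=feats)
    else:
        weekly = globals_ = triples = pd.DataFrame()

    phq = simulate_phq(traits, triples, config) if len(traits) else pd.DataFrame(
        columns=["participant_id", "week", "timestamp", "phq8"]
    )
    daily_observed = drop_days(daily_true, config) if len(daily_true) else daily_true

    truth = {
        "intercept": config.intercept,
        "effect_map": {k: list(v) for k, v in config.effect_map.items()},
        "covariate_effects": dict(config.covariate_effects),
        "random_effect_cov": [list(map(float, r)) for r in np.asarray(config.random_effect_cov)],
        "residual_sd": config.residual_sd,
        "seed": config.seed,
    }
    return SimulatedStudy(
        config, traits, daily_true, daily_observed, phq, weekly, globals_, triples, truth
    )


def render_cohort_events(study: SimulatedStudy, seed: int | None = None) -> pd.DataFrame:
    """Render observed daily records of every participant into event streams."""
    seed = study.config.seed if seed is None else seed
    parts = []
    for pid, d in study.daily_observed.groupby("participant_id", sort=True):
        # render contiguous runs so nights align with their actual next day
        d = d.sort_values("date")
        parts.append(render_event_streams(d, seed, study.config))
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def write_study(study: SimulatedStudy, events: pd.DataFrame | None, outdir, meta=None) -> dict:
    """Write study inputs as the pipeline's CSV/JSON interchange files."""
    from . import io as _io

    outdir = _io.ensure_dir(outdir)
    paths = {}
    if events is not None:
        ev = events.copy()
        ev["start_iso8601"] = ev.pop("start").dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        ev["end_iso8601"] = ev.pop("end").dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        paths["events"] = _io.write_csv(ev, outdir / "events.csv", meta)
    phq = study.phq.copy()
    phq["timestamp_iso8601"] = phq.pop("timestamp").dt.strftime("%Y-%m-%dT%H:%M:%S")
    paths["phq"] = _io.write_csv(phq, outdir / "phq.csv", meta)
    paths["covariates"] = _io.write_csv(
        study.traits[["participant_id", *COVARIATE_COLS]], outdir / "covariates.csv", meta
    )
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"_meta": meta or {}, **study.truth}, fh, indent=2)
    paths["ground_truth"] = truth_path
    return paths
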
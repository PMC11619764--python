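"""Daily behavioral feature extraction from passively sensed event streams.

Four streams are consumed — ``location`` (cluster-labelled visits with a
distance-from-home payload), ``pedometer`` (step-count bouts with cadence),
``activity`` (labelled activity bouts) and ``display`` (screen on/off
intervals).  From these we derive, per participant-day: sleep proxies
(bedtime, wake-up time, time in bed, number of sleep interruptions),
activity proxies (total step count per 1000 steps, walking rate in steps/s
within activity periods) and social-engagement proxies (normalized location
entropy, log number of location clusters, hours at home, log distance
traveled), together with per-stream and overall coverage.

All intervals are half-open ``[start, end)`` in participant-local clock
time.  Features that cannot be computed on a given day are reported as NaN,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STREAMS = ("location", "pedometer", "activity", "display")

#: Daily feature columns produced by :func:`extract_daily_features`.
DAILY_FEATURES = (
    "sleep_start",
    "wake_time",
    "time_in_bed",
    "n_interruptions",
    "step_count_k",
    "walking_rate",
    "norm_location_entropy",
    "n_location_clusters_log",
    "time_at_home",
    "dist_traveled_log",
)

HOUR = pd.Timedelta(hours=1)


class InputError(ValueError):
    """Raised for malformed sensor events."""


@dataclass
class SleepParams:
    """Tunable thresholds of the rest-window (sleep) detector.

    The main rest window is the longest display-off/uncovered gap whose
    start falls in ``[start_earliest, start_latest]`` and whose end falls in
    ``[end_earliest, end_latest]``, both expressed in hours since midnight
    of the *previous* day (so 19.0 = 19:00 yesterday, 28.0 = 04:00 today,
    38.0 = 14:00 today).  Display-on episodes no longer than
    ``bridge_max_min`` minutes are bridged across; bridged episodes of at
    least ``interruption_min_min`` minutes count as sleep interruptions.
    """

    start_earliest: float = 19.0
    start_latest: float = 28.0
    end_earliest: float = 27.0
    end_latest: float = 38.0
    min_window_h: float = 3.0
    bridge_max_min: float = 20.0
    interruption_min_min: float = 2.0


@dataclass
class ExtractionConfig:
    """Thresholds governing daily feature extraction."""

    sleep: SleepParams = field(default_factory=SleepParams)
    #: a day is valid when its overall coverage strictly exceeds this
    min_coverage: float = 0.0


@dataclass
class LocationDayProfile:
    """Dwell-time distribution over the location clusters visited in a day.

    ``p`` holds dwell fractions over visited clusters (sums to 1 when
    ``K >= 1``); ``dist_m`` is each cluster's time-weighted distance from
    home in meters.
    """

    cluster_ids: np.ndarray
    dwell_hours: np.ndarray
    p: np.ndarray
    dist_m: np.ndarray
    K: int
    home_cluster_id: int | None

    @property
    def empty(self) -> bool:
        return self.K == 0


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[float, float]]:
    """Union of half-open intervals given as float arrays (any unit)."""
    if len(starts) == 0:
        return []
    order = np.argsort(starts, kind="stable")
    merged: list[tuple[float, float]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _clip_hours(events: pd.DataFrame, day_start: pd.Timestamp, day_end: pd.Timestamp):
    """Event intervals clipped to [day_start, day_end), as float hours from day_start."""
    if len(events) == 0:
        return np.array([]), np.array([])
    s = (events["start"].clip(lower=day_start, upper=day_end) - day_start) / HOUR
    e = (events["end"].clip(lower=day_start, upper=day_end) - day_start) / HOUR
    keep = e > s
    return s.to_numpy()[keep.to_numpy()], e.to_numpy()[keep.to_numpy()]


def compute_coverage(
    events: pd.DataFrame, day_start: pd.Timestamp, day_end: pd.Timestamp
) -> dict[str, float]:
    """Per-stream and overall coverage of a (possibly non-24 h) day.

    Stream coverage is the summed duration of that stream's events, after
    merging overlaps and clipping to the day, divided by the day's elapsed
    duration; it is capped at 1.  Overall coverage is the arithmetic mean of
    the four stream coverages, streams with no events contributing 0.
    """
    if day_end <= day_start:
        raise InputError("day_end must be after day_start")
    if len(events) and (events["end"] < events["start"]).any():
        raise InputError("negative-duration event")
    total_h = (day_end - day_start) / HOUR
    out: dict[str, float] = {}
    for stream in STREAMS:
        ev = events[events["stream"] == stream]
        s, e = _clip_hours(ev, day_start, day_end)
        covered = sum(b - a for a, b in _merge_intervals(s, e))
        out[f"coverage_{stream}"] = min(covered / total_h, 1.0)
    out["coverage_overall"] = float(
        np.mean([out[f"coverage_{s}"] for s in STREAMS])
    )
    return out


def build_location_profile(
    location_events: pd.DataFrame,
    home_cluster_id: int | None,
    day_start: pd.Timestamp | None = None,
    day_end: pd.Timestamp | None = None,
) -> LocationDayProfile:
    """Aggregate cluster visits into a dwell-time profile.

    Dwell fractions are over located time only (time not covered by a
    location event contributes nothing).  An empty day yields ``K = 0`` and
    downstream location features become unavailable.
    """
    if len(location_events) == 0:
        return LocationDayProfile(
            np.array([], dtype=int), np.array([]), np.array([]), np.array([]), 0, home_cluster_id
        )
    ev = location_events
    if day_start is not None:
        s = (ev["start"].clip(lower=day_start, upper=day_end) - day_start) / HOUR
        e = (ev["end"].clip(lower=day_start, upper=day_end) - day_start) / HOUR
        dur = (e - s).clip(lower=0.0).to_numpy()
    else:
        dur = ((ev["end"] - ev["start"]) / HOUR).to_numpy()
    keep = dur > 0
    if not keep.any():
        return LocationDayProfile(
            np.array([], dtype=int), np.array([]), np.array([]), np.array([]), 0, home_cluster_id
        )
    cl = ev["cluster_id"].to_numpy()[keep].astype(int)
    dur = dur[keep]
    dist = ev["dist_home_m"].to_numpy(dtype=float)[keep]
    ids = np.unique(cl)
    dwell = np.array([dur[cl == c].sum() for c in ids])
    # time-weighted mean distance per cluster (constant per cluster in practice)
    dmean = np.array([np.average(dist[cl == c], weights=dur[cl == c]) for c in ids])
    p = dwell / dwell.sum()
    return LocationDayProfile(ids, dwell, p, dmean, int(len(ids)), home_cluster_id)


def normalized_entropy(profile: LocationDayProfile) -> float:
    """Normalized location entropy, −Σ p_k ln p_k / ln K ∈ [0, 1].

    Higher values mean time was spread more evenly across the clusters
    visited.  A single-cluster day has entropy 0 by definition; an empty
    profile yields NaN (feature unavailable).
    """
    if profile.empty:
        return float("nan")
    if profile.K == 1:
        return 0.0
    p = profile.p[profile.p > 0]
    h = -np.sum(p * np.log(p)) / np.log(profile.K)
    return float(min(max(h, 0.0), 1.0))


def time_at_home(profile: LocationDayProfile) -> float:
    """Total dwell hours in the home cluster; NaN if home is unknown."""
    if profile.empty or profile.home_cluster_id is None:
        return float("nan")
    mask = profile.cluster_ids == profile.home_cluster_id
    return float(profile.dwell_hours[mask].sum())


def distance_traveled(profile: LocationDayProfile) -> float:
    """log(1 + D) where D is the dwell-time-weighted mean distance from home.

    Weights are dwell fractions renormalized over non-home clusters; a day
    spent entirely at home returns 0.  NaN if home is unknown or the day has
    no located time.
    """
    if profile.empty or profile.home_cluster_id is None:
        return float("nan")
    away = profile.cluster_ids != profile.home_cluster_id
    total_away = profile.dwell_hours[away].sum()
    if total_away <= 0:
        return 0.0
    w = profile.dwell_hours[away] / total_away
    d = float(np.sum(w * profile.dist_m[away]))
    return float(np.log1p(d))


def infer_home_cluster(location_events: pd.DataFrame) -> int | None:
    """Home = cluster with the greatest cumulative 00:00–06:00 dwell time.

    Ties break to the smallest cluster id.  Returns None when no nighttime
    located data exist in the window.
    """
    if len(location_events) == 0:
        return None
    totals: dict[int, float] = {}
    for _, row in location_events.iterrows():
        s, e = row["start"], row["end"]
        day = s.normalize()
        last = e.normalize()
        while day <= last:
            lo = max(s, day)
            hi = min(e, day + pd.Timedelta(hours=6))
            if hi > lo:
                c = int(row["cluster_id"])
                totals[c] = totals.get(c, 0.0) + (hi - lo) / HOUR
            day += pd.Timedelta(days=1)
    if not totals:
        return None
    best = max(totals.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def _on_intervals(display_events: pd.DataFrame, span_start: pd.Timestamp, span_end: pd.Timestamp):
    if len(display_events) == 0:
        return []
    ev = display_events[display_events["display_on"].astype(bool)]
    s, e = _clip_hours(ev, span_start, span_end)
    return _merge_intervals(s, e)


def extract_sleep_features(
    display_events: pd.DataFrame,
    day: pd.Timestamp,
    params: SleepParams | None = None,
) -> dict[str, float] | None:
    """Detect the main rest window ending on ``day`` from display events.

    The search span runs from 12:00 of the previous day to 14:00 of
    ``day``.  Gaps are maximal periods not covered by a display-on event
    (display-off events and uncovered time are treated alike); gaps
    separated by short display-on episodes (≤ ``bridge_max_min`` minutes)
    are bridged into one candidate window.  Returns None when no qualifying
    window of at least ``min_window_h`` hours exists.

    ``sleep_start`` is reported in hours since midnight of the previous day
    (e.g. 23.0 = 23:00 yesterday, 25.5 = 01:30 today) so that day-to-day
    variability statistics are not corrupted by the midnight wrap;
    ``wake_time`` is in hours since midnight of ``day``.
    """
    p = params or SleepParams()
    day = pd.Timestamp(day).normalize()
    prev_midnight = day - pd.Timedelta(days=1)
    span_start = prev_midnight + pd.Timedelta(hours=12)
    span_end = day + pd.Timedelta(hours=p.end_latest - 24.0)
    on = _on_intervals(display_events, span_start, span_end)
    span_h = (span_end - span_start) / HOUR
    offset = 12.0  # span coordinates -> hours since prev midnight

    # complement of on-intervals within the span -> raw gaps
    gaps: list[tuple[float, float]] = []
    cursor = 0.0
    for s, e in on:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span_h:
        gaps.append((cursor, span_h))
    if not gaps:
        return None

    # bridge gaps across short on-episodes, tracking bridged episodes
    windows: list[tuple[float, float, list[tuple[float, float]]]] = []
    ws, we = gaps[0]
    bridged: list[tuple[float, float]] = []
    for s, e in gaps[1:]:
        sep = s - we  # duration of the on-episode between gaps
        if sep * 60.0 <= p.bridge_max_min:
            bridged.append((we, s))
            we = e
        else:
            windows.append((ws, we, bridged))
            ws, we, bridged = s, e, []
    windows.append((ws, we, bridged))

    best = None
    for ws, we, eps in windows:
        start_h = ws + offset
        end_h = we + offset
        if not (p.start_earliest <= start_h <= p.start_latest):
            continue
        if not (p.end_earliest <= end_h <= p.end_latest):
            continue
        if end_h - start_h < p.min_window_h:
            continue
        # the window must not begin at the (uncovered) span edge artifact:
        # a gap opening exactly at span start has unknown true onset
        if ws == 0.0:
            continue
        length = we - ws
        if best is None or length > best[0] or (length == best[0] and ws < best[1][0]):
            best = (length, (ws, we, eps))
    if best is None:
        return None
    ws, we, eps = best[1]
    n_int = sum(1 for a, b in eps if (b - a) * 60.0 >= p.interruption_min_min)
    sleep_start = ws + offset
    wake = we + offset - 24.0
    return {
        "sleep_start": float(sleep_start),
        "wake_time": float(wake),
        "time_in_bed": float(we - ws),
        "n_interruptions": float(n_int),
    }


def extract_activity_features(
    pedometer_events: pd.DataFrame, activity_events: pd.DataFrame
) -> dict[str, float]:
    """Total step count (per 1000) and walking rate within activity bouts.

    Walking rate divides the steps of pedometer events overlapping a
    ``walking`` activity bout by the summed bout duration in seconds; it is
    NaN when no walking bouts exist.
    """
    steps = float(pedometer_events["steps"].sum()) if len(pedometer_events) else 0.0
    bouts = activity_events[activity_events["bout"] == "walking"] if len(activity_events) else activity_events
    if len(bouts) == 0:
        return {"step_count_k": steps / 1000.0, "walking_rate": float("nan")}
    bout_s = ((bouts["end"] - bouts["start"]) / pd.Timedelta(seconds=1)).sum()
    if bout_s <= 0:
        return {"step_count_k": steps / 1000.0, "walking_rate": float("nan")}
    in_bout = 0.0
    bs = bouts["start"].to_numpy()
    be = bouts["end"].to_numpy()
    for _, ev in pedometer_events.iterrows():
        if ((ev["start"].to_datetime64() < be) & (ev["end"].to_datetime64() > bs)).any():
            in_bout += float(ev["steps"])
    return {"step_count_k": steps / 1000.0, "walking_rate": in_bout / bout_s}


def extract_daily_features(
    events: pd.DataFrame,
    participant_id,
    date: pd.Timestamp,
    home_cluster_id: int | None = None,
    config: ExtractionConfig | None = None,
    day_start: pd.Timestamp | None = None,
    day_end: pd.Timestamp | None = None,
) -> dict:
    """Extract one participant-day's feature record.

    ``events`` must contain (at least) this participant's events from the
    previous afternoon through the end of ``date``; sleep detection looks
    back across midnight.  ``day_start``/``day_end`` default to local
    midnight-to-midnight; travel days may pass an elapsed window of other
    length, which is used as the coverage denominator.
    """
    cfg = config or ExtractionConfig()
    date = pd.Timestamp(date).normalize()
    if day_start is None:
        day_start = date
    if day_end is None:
        day_end = date + pd.Timedelta(days=1)
    ev = events[events["participant_id"] == participant_id] if "participant_id" in events else events
    in_day = ev[(ev["end"] > day_start) & (ev["start"] < day_end)]

    rec: dict = {"participant_id": participant_id, "date": date}
    rec.update(compute_coverage(in_day, day_start, day_end))

    for name in DAILY_FEATURES:
        rec[name] = float("nan")

    sleep = extract_sleep_features(ev[ev["stream"] == "display"], date, cfg.sleep)
    if sleep is not None:
        rec.update(sleep)

    ped = in_day[in_day["stream"] == "pedometer"]
    act = in_day[in_day["stream"] == "activity"]
    if rec["coverage_pedometer"] > 0:
        rec.update(extract_activity_features(ped, act))

    loc = in_day[in_day["stream"] == "location"]
    profile = build_location_profile(loc, home_cluster_id, day_start, day_end)
    if not profile.empty:
        rec["norm_location_entropy"] = normalized_entropy(profile)
        rec["n_location_clusters_log"] = float(np.log1p(profile.K))
        if home_cluster_id is not None:
            rec["time_at_home"] = time_at_home(profile)
            rec["dist_traveled_log"] = distance_traveled(profile)

    any_feature = any(np.isfinite(rec[name]) for name in DAILY_FEATURES)
    rec["valid_day"] = bool(rec["coverage_overall"] > cfg.min_coverage and any_feature)
    return rec


def extract_cohort(events: pd.DataFrame, config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Run daily extraction over every participant-day present in ``events``.

    The home cluster is inferred per participant from nighttime dwell over
    the whole window.  Returns one row per participant-day, ordered by
    participant and date; unavailable features are NaN.
    """
    cfg = config or ExtractionConfig()
    records = []
    for pid, ev in events.groupby("participant_id", sort=True):
        home = infer_home_cluster(ev[ev["stream"] == "location"])
        # days with any non-display evidence (display spills into the
        # previous evening by construction of the night window)
        anchor = ev[ev["stream"] != "display"]
        if len(anchor) == 0:
            anchor = ev
        days = pd.to_datetime(anchor["start"]).dt.normalize().unique()
        for day in sorted(days):
            records.append(
                extract_daily_features(ev, pid, day, home_cluster_id=home, config=cfg)
            )
    if not records:
        return pd.DataFrame()
    return pd.DataFrame.from_records(records).sort_values(
        ["participant_id", "date"], kind="stable"
    ).reset_index(drop=True)
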
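"""Unit and property tests for daily feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bvitals import (
    LocationDayProfile,
    build_location_profile,
    compute_coverage,
    distance_traveled,
    extract_activity_features,
    extract_daily_features,
    extract_sleep_features,
    infer_home_cluster,
    normalized_entropy,
    time_at_home,
)
from bvitals.features import InputError, _merge_intervals

DAY = pd.Timestamp("2023-01-10")


def profile_from_p(p, dists=None, home=0):
    p = np.asarray(p, dtype=float)
    return LocationDayProfile(
        cluster_ids=np.arange(len(p)),
        dwell_hours=p * 24.0,
        p=p,
        dist_m=np.asarray(dists if dists is not None else np.zeros(len(p)), dtype=float),
        K=len(p),
        home_cluster_id=home,
    )


def brute_force_entropy(p):
    """Independent oracle: -sum p ln p / ln K, K = 1 defined as 0."""
    p = [x for x in p if x > 0]
    if len(p) <= 1:
        return 0.0
    return -sum(x * np.log(x) for x in p) / np.log(len(p))


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0], 0.0),
            ([0.7, 0.2, 0.1], 0.7299),  # hand oracle: -sum p ln p / ln 3
        ],
    )
    def test_known_values(self, p, expected):
        assert normalized_entropy(profile_from_p(p)) == pytest.approx(expected, abs=1e-4)

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = rng.integers(1, 9)
            w = rng.dirichlet(np.full(k, rng.uniform(0.2, 3.0)))
            assert normalized_entropy(profile_from_p(w)) == pytest.approx(
                brute_force_entropy(w), abs=1e-12
            )

    def test_relabeling_invariance_and_monotone_approach_to_uniform(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(5))
        assert normalized_entropy(profile_from_p(p)) == pytest.approx(
            normalized_entropy(profile_from_p(p[::-1])), abs=1e-14
        )
        # two-cluster split: entropy increases toward (0.5, 0.5)
        values = [
            normalized_entropy(profile_from_p([q, 1 - q])) for q in np.linspace(0.05, 0.5, 20)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0)

    def test_empty_profile_is_unavailable_not_a_crash(self):
        empty = build_location_profile(
            pd.DataFrame(columns=["start", "end", "cluster_id", "dist_home_m"]), home_cluster_id=0
        )
        assert empty.K == 0
        assert np.isnan(normalized_entropy(empty))


class TestCoverage:
    def test_full_display_only(self, events_factory):
        ev = events_factory(
            [("display", DAY, DAY + pd.Timedelta(days=1), {"display_on": False})]
        )
        cov = compute_coverage(ev, DAY, DAY + pd.Timedelta(days=1))
        assert cov["coverage_display"] == 1.0
        assert cov["coverage_overall"] == 0.25

    def test_each_stream_half_day(self, events_factory):
        rows = [
            (s, DAY, DAY + pd.Timedelta(hours=12), {})
            for s in ("location", "pedometer", "activity", "display")
        ]
        cov = compute_coverage(events_factory(rows), DAY, DAY + pd.Timedelta(days=1))
        assert cov["coverage_overall"] == pytest.approx(0.5)

    def test_23h_travel_day_fully_covered(self, events_factory):
        # eastward travel: the elapsed local day is 23 h and is the denominator
        day_end = DAY + pd.Timedelta(hours=23)
        rows = [(s, DAY, day_end, {}) for s in ("location", "pedometer", "activity", "display")]
        cov = compute_coverage(events_factory(rows), DAY, day_end)
        assert all(cov[f"coverage_{s}"] == 1.0 for s in ("location", "pedometer", "activity", "display"))

    def test_overlapping_events_never_exceed_one(self, events_factory):
        rows = [
            ("pedometer", DAY, DAY + pd.Timedelta(hours=20), {}),
            ("pedometer", DAY + pd.Timedelta(hours=5), DAY + pd.Timedelta(hours=23), {}),
            ("pedometer", DAY + pd.Timedelta(hours=10), DAY + pd.Timedelta(hours=24), {}),
        ]
        cov = compute_coverage(events_factory(rows), DAY, DAY + pd.Timedelta(days=1))
        assert cov["coverage_pedometer"] == 1.0

    def test_negative_duration_rejected(self, events_factory):
        ev = events_factory([("display", DAY + pd.Timedelta(hours=2), DAY, {})])
        with pytest.raises(InputError):
            compute_coverage(ev, DAY, DAY + pd.Timedelta(days=1))

    @given(
        st.lists(
            st.tuples(st.floats(0, 23), st.floats(0.01, 12)).map(
                lambda t: (t[0], min(t[0] + t[1], 24.0))
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_union_bounds(self, intervals):
        s = np.array([a for a, _ in intervals])
        e = np.array([b for _, b in intervals])
        merged = _merge_intervals(s, e)
        total = sum(b - a for a, b in merged)
        assert 0 <= total <= 24.0 + 1e-9
        assert total <= sum(e - s) + 1e-9
        assert total >= max(e - s) - 1e-9


class TestLocationFeatures:
    def test_dwell_ratios(self, events_factory):
        rows = [
            ("location", DAY, DAY + pd.Timedelta(hours=16.8), {"cluster_id": 3, "dist_home_m": 0.0}),
            ("location", DAY + pd.Timedelta(hours=16.8), DAY + pd.Timedelta(hours=21.6),
             {"cluster_id": 1, "dist_home_m": 500.0}),
            ("location", DAY + pd.Timedelta(hours=21.6), DAY + pd.Timedelta(hours=24),
             {"cluster_id": 2, "dist_home_m": 1500.0}),
        ]
        prof = build_location_profile(events_factory(rows), home_cluster_id=3)
        assert prof.K == 3
        assert sorted(prof.p, reverse=True) == pytest.approx([0.7, 0.2, 0.1])
        assert time_at_home(prof) == pytest.approx(16.8)

    def test_single_cluster_day(self, events_factory):
        rows = [("location", DAY, DAY + pd.Timedelta(hours=24), {"cluster_id": 0, "dist_home_m": 0.0})]
        prof = build_location_profile(events_factory(rows), home_cluster_id=0)
        assert prof.K == 1 and prof.p[0] == 1.0
        assert normalized_entropy(prof) == 0.0
        assert time_at_home(prof) == pytest.approx(24.0)
        assert distance_traveled(prof) == 0.0

    def test_distance_single_and_equal_weight(self):
        one = profile_from_p([1.0], dists=[1000.0], home=99)
        one.home_cluster_id = 99  # not visited -> all located time is away
        assert distance_traveled(one) == pytest.approx(np.log(1001.0), abs=1e-9)
        two = profile_from_p([0.5, 0.5], dists=[500.0, 1500.0], home=99)
        assert distance_traveled(two) == pytest.approx(np.log(1001.0), abs=1e-9)

    def test_home_visits_sum(self, events_factory):
        rows = [
            ("location", DAY, DAY + pd.Timedelta(hours=8), {"cluster_id": 0, "dist_home_m": 0.0}),
            ("location", DAY + pd.Timedelta(hours=12), DAY + pd.Timedelta(hours=14.5),
             {"cluster_id": 0, "dist_home_m": 0.0}),
            ("location", DAY + pd.Timedelta(hours=9), DAY + pd.Timedelta(hours=10),
             {"cluster_id": 4, "dist_home_m": 800.0}),
        ]
        prof = build_location_profile(events_factory(rows), home_cluster_id=0)
        assert time_at_home(prof) == pytest.approx(10.5)


class TestHomeInference:
    def test_nighttime_argmax_and_tiebreak(self, events_factory):
        rows = []
        for d in range(3):
            day = DAY + pd.Timedelta(days=d)
            rows.append(("location", day, day + pd.Timedelta(hours=5), {"cluster_id": 7, "dist_home_m": 0.0}))
            rows.append(("location", day + pd.Timedelta(hours=10), day + pd.Timedelta(hours=20),
                         {"cluster_id": 2, "dist_home_m": 100.0}))
        assert infer_home_cluster(events_factory(rows)) == 7
        # equal nighttime dwell -> smaller id wins
        tie = events_factory(
            [
                ("location", DAY, DAY + pd.Timedelta(hours=3), {"cluster_id": 5, "dist_home_m": 0}),
                ("location", DAY + pd.Timedelta(hours=3), DAY + pd.Timedelta(hours=6),
                 {"cluster_id": 2, "dist_home_m": 0}),
            ]
        )
        assert infer_home_cluster(tie) == 2

    def test_no_nighttime_data(self, events_factory):
        ev = events_factory(
            [("location", DAY + pd.Timedelta(hours=10), DAY + pd.Timedelta(hours=12),
              {"cluster_id": 1, "dist_home_m": 0})]
        )
        assert infer_home_cluster(ev) is None


def display_day(events_factory, segments):
    """segments: (state, start_hour_rel_prev_midnight, end_hour) on a 12–38 axis."""
    base = DAY - pd.Timedelta(days=1)
    return events_factory(
        [
            ("display", base + pd.Timedelta(hours=s), base + pd.Timedelta(hours=e),
             {"display_on": state})
            for state, s, e in segments
        ]
    )


class TestSleepDetection:
    def test_plain_night(self, events_factory):
        ev = display_day(events_factory, [(True, 12, 23), (False, 23, 31), (True, 31, 38)])
        out = extract_sleep_features(ev, DAY)
        assert out["sleep_start"] == pytest.approx(23.0)
        assert out["wake_time"] == pytest.approx(7.0)
        assert out["time_in_bed"] == pytest.approx(8.0)
        assert out["n_interruptions"] == 0

    def test_bridged_interruption_keeps_window(self, events_factory):
        ev = display_day(
            events_factory,
            [(True, 12, 23), (False, 23, 27), (True, 27, 27 + 5 / 60), (False, 27 + 5 / 60, 31),
             (True, 31, 38)],
        )
        out = extract_sleep_features(ev, DAY)
        assert out["sleep_start"] == pytest.approx(23.0)
        assert out["time_in_bed"] == pytest.approx(8.0)
        assert out["n_interruptions"] == 1

    def test_longest_qualifying_gap_wins(self, events_factory):
        # off 22:00-06:00 and off 13:00-14:00 next day: main window is the long one
        ev = display_day(
            events_factory,
            [(True, 12, 22), (False, 22, 30), (True, 30, 37), (False, 37, 38)],
        )
        out = extract_sleep_features(ev, DAY)
        assert out["sleep_start"] == pytest.approx(22.0)
        assert out["wake_time"] == pytest.approx(6.0)

    def test_no_qualifying_gap(self, events_factory):
        ev = display_day(events_factory, [(True, 12, 38)])
        assert extract_sleep_features(ev, DAY) is None

    def test_agrees_with_exhaustive_enumeration(self, events_factory):
        """Randomized small instances against a brute-force gap enumerator."""
        rng = np.random.default_rng(3)
        for _ in range(60):
            cuts = np.sort(rng.uniform(12, 38, rng.integers(4, 10)))
            cuts = np.concatenate([[12.0], cuts, [38.0]])
            first_on = bool(rng.integers(2))
            segs = []
            for i in range(len(cuts) - 1):
                segs.append((first_on if i % 2 == 0 else not first_on, cuts[i], cuts[i + 1]))
            ev = display_day(events_factory, segs)
            got = extract_sleep_features(ev, DAY)

            # oracle: enumerate bridged gap windows directly from segments
            gaps = [(s, e) for on, s, e in segs if not on]
            merged = []
            for s, e in gaps:
                if merged and (s - merged[-1][1]) <= 20 / 60 + 1e-12:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            cands = [
                (e - s, s, e)
                for s, e in merged
                if 19 <= s <= 28 and 27 <= e <= 38 and e - s >= 3 and s > 12
            ]
            if not cands:
                assert got is None
            else:
                L, s, e = max(cands, key=lambda c: (c[0], -c[1]))
                assert got is not None
                assert got["sleep_start"] == pytest.approx(s, abs=1e-9)
                assert got["time_in_bed"] == pytest.approx(L, abs=1e-9)


class TestActivityFeatures:
    def test_step_scaling_and_rate(self, events_factory):
        ev = events_factory(
            [
                ("pedometer", DAY + pd.Timedelta(hours=10), DAY + pd.Timedelta(hours=11),
                 {"steps": 3600.0, "cadence_steps_per_s": 1.0}),
                ("activity", DAY + pd.Timedelta(hours=10), DAY + pd.Timedelta(hours=11),
                 {"bout": "walking"}),
            ]
        )
        out = extract_activity_features(
            ev[ev["stream"] == "pedometer"], ev[ev["stream"] == "activity"]
        )
        assert out["step_count_k"] == pytest.approx(3.6)
        assert out["walking_rate"] == pytest.approx(1.0)

    def test_no_pedometer_events(self, events_factory):
        empty = events_factory([]) if False else pd.DataFrame(
            columns=["start", "end", "steps", "bout", "stream"]
        )
        out = extract_activity_features(empty, empty)
        assert out["step_count_k"] == 0.0
        assert np.isnan(out["walking_rate"])

    def test_steps_of_8500(self, events_factory):
        ev = events_factory(
            [("pedometer", DAY + pd.Timedelta(hours=9), DAY + pd.Timedelta(hours=10),
              {"steps": 8500.0})]
        )
        out = extract_activity_features(ev, pd.DataFrame(columns=["start", "end", "bout"]))
        assert out["step_count_k"] == pytest.approx(8.5)


class TestDailyRecord:
    def test_empty_day_invalid(self, events_factory):
        ev = pd.DataFrame(
            columns=["participant_id", "stream", "start", "end", "cluster_id",
                     "dist_home_m", "steps", "cadence_steps_per_s", "display_on", "bout"]
        )
        rec = extract_daily_features(ev, 1, DAY)
        assert rec["valid_day"] is False
        from bvitals import DAILY_FEATURES
        assert all(np.isnan(rec[f]) for f in DAILY_FEATURES)

    def test_pedometer_only_day(self, events_factory):
        ev = events_factory(
            [("pedometer", DAY, DAY + pd.Timedelta(hours=24), {"steps": 5000.0})]
        )
        rec = extract_daily_features(ev, 1, DAY)
        assert rec["step_count_k"] == pytest.approx(5.0)
        assert np.isnan(rec["norm_location_entropy"])
        assert np.isnan(rec["sleep_start"])
        assert rec["coverage_overall"] == pytest.approx(0.25)
        assert rec["valid_day"] is True

    def test_order_insensitivity(self, small_config, small_traits):
        from bvitals import render_event_streams, extract_daily_features
        from bvitals import simulate_daily_features

        daily = simulate_daily_features(small_traits.iloc[1], 3, 5, small_config)
        ev = render_event_streams(daily, 5, small_config)
        shuffled = ev.sample(frac=1.0, random_state=0).reset_index(drop=True)
        day = daily["date"].iloc[1]
        home = 0
        a = extract_daily_features(ev, ev["participant_id"].iloc[0], day, home_cluster_id=home)
        b = extract_daily_features(shuffled, ev["participant_id"].iloc[0], day, home_cluster_id=home)
        for k, v in a.items():
            if isinstance(v, float) and np.isnan(v):
                assert np.isnan(b[k])
            else:
                assert b[k] == pytest.approx(v) if isinstance(v, float) else b[k] == v
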
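"""Feeding classification rules, event assembly, FDP computation and the
truth-ledger round trip."""

import numpy as np
import pandas as pd
import pytest

from fdpscan import feedscan
from fdpscan.config import Thresholds
from fdpscan.trackmetrics import STOP_COLUMNS


def make_stop(animal="a", date="2010-03-01", start="12:00", end="14:00",
              x=10_000.0, y=0.0, eating=0, running=0, standing=4):
    row = dict.fromkeys(STOP_COLUMNS, 0)
    row.update(animal_id=animal, date=pd.Timestamp(date),
               start=pd.Timestamp(f"{date} {start}"),
               end=pd.Timestamp(f"{date} {end}"),
               x_m=x, y_m=y, duration_min=120.0, n_fixes=12,
               roost_candidate=False, n_eating=eating, n_running=running,
               n_standing=standing)
    return row


def stops_frame(rows):
    return pd.DataFrame(rows, columns=STOP_COLUMNS)


EMPTY_SITES = pd.DataFrame(columns=["site_id", "kind", "x_m", "y_m", "radius_m"])


def full_daily(animals, start="2010-03-01", n_days=20):
    dates = pd.date_range(start, periods=n_days)
    rows = [{"animal_id": a, "date": d, "missing_day": False,
             "active": True, "travel_km": 50.0, "max_disp_km": 15.0,
             "straightness": 0.6, "mean_speed": 10.0, "flight_elev_m": 400.0,
             "departure_h": 3.0, "prop_active_flight": 0.15}
            for a in animals for d in dates]
    return pd.DataFrame(rows)


class TestClassifyStop:
    def test_multiple_eating_bursts_is_feeding(self):
        cl = feedscan.classify_stops(stops_frame([make_stop(eating=3)]),
                                     EMPTY_SITES)
        assert cl["classification"].iloc[0] == "feeding"

    def test_single_eating_with_running_pair_is_feeding(self):
        cl = feedscan.classify_stops(
            stops_frame([make_stop(eating=1, running=2)]), EMPTY_SITES)
        assert cl["classification"].iloc[0] == "feeding"

    def test_single_eating_single_running_is_undecided(self):
        cl = feedscan.classify_stops(
            stops_frame([make_stop(eating=1, running=1)]), EMPTY_SITES)
        assert cl["classification"].iloc[0] == "undecided"

    def test_eating_inside_roost_site_is_never_feeding(self):
        sites = pd.DataFrame([{"site_id": "r0", "kind": "roost",
                               "x_m": 10_000.0, "y_m": 0.0, "radius_m": 400.0}])
        cl = feedscan.classify_stops(stops_frame([make_stop(eating=3)]), sites)
        assert bool(cl["in_roost"].iloc[0])
        assert cl["classification"].iloc[0] == "none"

    def test_lone_eating_with_cofeeder_is_feeding(self):
        # rule iii: another animal's rule-i stop overlaps in time and space
        rows = [make_stop(animal="a", eating=3),
                make_stop(animal="b", eating=1, start="12:30", end="13:30",
                          x=10_150.0)]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        assert list(cl["classification"]) == ["feeding", "feeding"]

    def test_lone_eating_without_cofeeder_is_none(self):
        rows = [make_stop(animal="b", eating=1)]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        assert cl["classification"].iloc[0] == "none"

    def test_cofeeding_requires_temporal_overlap(self):
        rows = [make_stop(animal="a", eating=3, start="06:00", end="07:00"),
                make_stop(animal="b", eating=1, start="12:00", end="13:00")]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        assert list(cl["classification"]) == ["feeding", "none"]

    def test_two_pass_is_order_independent(self):
        rows = [make_stop(animal="a", eating=3),
                make_stop(animal="b", eating=1, x=10_100.0),
                make_stop(animal="c", eating=1, running=1, x=30_000.0),
                make_stop(animal="d", eating=0, x=40_000.0)]
        base = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        shuffled = stops_frame(rows).sample(frac=1, random_state=7)
        other = feedscan.classify_stops(shuffled, EMPTY_SITES)
        merged = other.set_index("animal_id")["classification"]
        for aid, want in base.set_index("animal_id")["classification"].items():
            assert merged[aid] == want

    def test_tightening_rules_never_creates_events(self, small_metrics,
                                                   small_dataset):
        """Monotone conservatism: stricter burst thresholds can only shrink
        the feeding-event set."""
        _, stops = small_metrics
        sites = small_dataset.sites
        n_prev = None
        for min_eat in (2, 3, 4):
            th = Thresholds(min_eating_alone=min_eat)
            ev = feedscan.build_feeding_events(
                feedscan.classify_stops(stops, sites, th), sites)
            if n_prev is not None:
                assert len(ev) <= n_prev
            n_prev = len(ev)


class TestEventsAndFdp:
    def test_two_feeding_stops_collapse_to_one_event(self):
        rows = [make_stop(eating=3, start="08:00", end="10:00"),
                make_stop(eating=2, start="13:00", end="15:00", x=20_000.0)]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        ev = feedscan.build_feeding_events(cl, EMPTY_SITES)
        assert len(ev) == 1

    def test_at_sfs_resolved_by_station_radius(self):
        sites = pd.DataFrame([{"site_id": "s0", "kind": "sfs",
                               "x_m": 10_050.0, "y_m": 0.0, "radius_m": 200.0}])
        cl = feedscan.classify_stops(stops_frame([make_stop(eating=3)]), sites)
        ev = feedscan.build_feeding_events(cl, sites)
        assert bool(ev["at_sfs"].iloc[0])

    def _events(self, dates, animal="a"):
        rows = [make_stop(date=d, eating=3) for d in dates]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        return feedscan.build_feeding_events(cl, EMPTY_SITES), cl

    def test_consecutive_feeding_days_give_fdp_zero(self):
        ev, cl = self._events(["2010-03-01", "2010-03-02"])
        out = feedscan.compute_fdp(ev, full_daily(["a"]), cl)
        assert out["fdp"].iloc[1] == 0 and out["valid"].iloc[1]

    def test_three_intervening_days_give_fdp_three(self):
        ev, cl = self._events(["2010-03-01", "2010-03-05"])
        out = feedscan.compute_fdp(ev, full_daily(["a"]), cl)
        assert out["fdp"].iloc[1] == 3

    def test_first_event_has_unknown_history(self):
        ev, cl = self._events(["2010-03-01", "2010-03-02"])
        out = feedscan.compute_fdp(ev, full_daily(["a"]), cl)
        assert out["exclusion_reason"].iloc[0] == "unknown_history"
        assert not out["valid"].iloc[0]

    def test_gap_beyond_two_weeks_is_excluded(self):
        ev, cl = self._events(["2010-03-01", "2010-03-18"])
        out = feedscan.compute_fdp(ev, full_daily(["a"], n_days=30), cl)
        assert out["fdp"].iloc[1] == 16
        assert out["exclusion_reason"].iloc[1] == "fdp_over_14"

    def test_missing_day_inside_gap_excludes_event(self):
        ev, cl = self._events(["2010-03-01", "2010-03-05"])
        daily = full_daily(["a"])
        daily.loc[daily["date"] == "2010-03-03", "missing_day"] = True
        out = feedscan.compute_fdp(ev, daily, cl)
        assert out["exclusion_reason"].iloc[1] == "missing_day_in_gap"

    def test_undecided_day_inside_gap_excludes_event(self):
        rows = [make_stop(date="2010-03-01", eating=3),
                make_stop(date="2010-03-03", eating=1, running=1),
                make_stop(date="2010-03-05", eating=3)]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        ev = feedscan.build_feeding_events(cl, EMPTY_SITES)
        out = feedscan.compute_fdp(ev, full_daily(["a"]), cl)
        assert out["exclusion_reason"].iloc[1] == "undecided_in_gap"

    def test_undecided_on_the_feeding_day_itself_does_not_exclude(self):
        rows = [make_stop(date="2010-03-01", eating=3),
                make_stop(date="2010-03-05", eating=1, running=1,
                          start="08:00", end="09:00", x=30_000.0),
                make_stop(date="2010-03-05", eating=3)]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        ev = feedscan.build_feeding_events(cl, EMPTY_SITES)
        out = feedscan.compute_fdp(ev, full_daily(["a"]), cl)
        assert out["valid"].iloc[1]


class TestSequencesAndHistogram:
    def _valid_events(self, pairs):
        rows = []
        for animal, dates in pairs.items():
            rows += [make_stop(animal=animal, date=d, eating=3) for d in dates]
        cl = feedscan.classify_stops(stops_frame(rows), EMPTY_SITES)
        ev = feedscan.build_feeding_events(cl, EMPTY_SITES)
        return feedscan.compute_fdp(ev, full_daily(list(pairs), n_days=31), cl)

    def test_sequence_shape_and_categories(self):
        ev = self._valid_events({"a": ["2010-03-01", "2010-03-02",
                                       "2010-03-07", "2010-03-13",
                                       "2010-03-21"]})
        seq = feedscan.build_sequences(ev, full_daily(["a"], n_days=31))
        by_event = seq.groupby("event_id")
        lengths = by_event["length"].first().sort_values()
        assert list(lengths) == [0, 4, 5, 7]
        cats = by_event["category"].first()
        assert set(cats) == {"zero", "short", "mid", "long"}
        for _, grp in by_event:
            assert list(grp["day_index"]) == list(range(grp["length"].iloc[0] + 1))

    def test_histogram_counts_and_monthly_long_proportion(self):
        ev = self._valid_events({"a": ["2010-03-01", "2010-03-02",
                                       "2010-03-03", "2010-03-05",
                                       "2010-03-09"]})
        counts, monthly = feedscan.fdp_histogram(ev)
        # valid FDPs: 0, 0, 1, 3
        assert counts[0] == 2 and counts[1] == 1 and counts[3] == 1
        assert counts.sum() == 4
        march = monthly.loc[monthly["month"] == 3].iloc[0]
        assert march["n_events"] == 4 and march["prop_long"] == 0.0

    def test_empty_event_table_gives_zero_histogram(self):
        counts, monthly = feedscan.fdp_histogram(
            pd.DataFrame(columns=feedscan.EVENT_COLUMNS))
        assert counts.sum() == 0

    def test_subset_selector(self):
        ev = pd.DataFrame({"animal_id": ["a", "a"],
                           "date": pd.to_datetime(["2010-03-01", "2010-03-05"]),
                           "at_sfs": [True, False], "valid": [True, True],
                           "fdp": [1, 3], "x_m": 0.0, "y_m": 0.0,
                           "exclusion_reason": "none"})
        assert len(feedscan.subset_events(ev, "sfs")) == 1
        assert len(feedscan.subset_events(ev, "occasional")) == 1
        assert len(feedscan.subset_events(ev, "all")) == 2
        with pytest.raises(ValueError):
            feedscan.subset_events(ev, "bogus")


class TestTruthRoundTrip:
    def test_detected_feeding_days_match_truth_exactly(self, small_dataset,
                                                       small_metrics):
        """At zero label noise the pipeline recovers the generator's feeding
        days and deprivation gaps exactly."""
        ds = small_dataset
        daily, stops = small_metrics
        cl = feedscan.classify_stops(stops, ds.sites)
        ev = feedscan.compute_fdp(
            feedscan.build_feeding_events(cl, ds.sites), daily, cl)
        truth_days = {(r.animal_id, r.date)
                      for r in ds.truth.loc[ds.truth["feeding"]].itertuples()}
        event_days = {(r.animal_id, r.date) for r in ev.itertuples()}
        assert event_days == truth_days

        # recovered FDPs equal the truth gaps wherever the FDP is known
        truth_sorted = ds.truth.loc[ds.truth["feeding"]].sort_values(
            ["animal_id", "date"])
        gaps = {}
        for aid, grp in truth_sorted.groupby("animal_id"):
            dates = list(grp["date"])
            for prev, cur in zip(dates, dates[1:]):
                gaps[(aid, cur)] = (cur - prev).days - 1
        for r in ev.itertuples():
            if np.isfinite(r.fdp):
                assert gaps[(r.animal_id, r.date)] == int(r.fdp)
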
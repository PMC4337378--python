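"""Feeding-event identification and food-deprivation-period assembly.

Day-stops are classified with three conservative rules designed to keep
false-positive feeding detections rare:

  i.   two or more ``eating`` bursts during the stop;
  ii.  a single ``eating`` burst accompanied by two or more ``running``
       bursts (fighting/hopping at a carcass);
  iii. a single ``eating`` burst coinciding in time and space with another
       tagged animal's rule-i/ii feeding stop.

A single ``eating`` with a single ``running`` burst is *undecided*; stops
inside major roost sites are never feeding (carcasses do not occur there).
Feeding is resolved at day granularity.  The food-deprivation period (FDP)
of a feeding event is the number of whole non-feeding days since the
animal's previous feeding event; events whose gap contains a missing or
undecided day, whose history is unknown, or whose FDP exceeds two weeks are
excluded from analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Thresholds

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["animal_id", "date", "x_m", "y_m", "at_sfs",
                 "fdp", "valid", "exclusion_reason"]

EXCLUSION_REASONS = ("none", "unknown_history", "missing_day_in_gap",
                     "undecided_in_gap", "fdp_over_14")


def classify_stop(stop, roost_mask: bool, co_feeding_index,
                  thresholds: Thresholds | None = None) -> str:
    """Classify one day-stop as ``feeding`` / ``undecided`` / ``none``.

    ``co_feeding_index`` is an iterable of other animals' already-classified
    feeding stops, each a mapping with animal_id, start, end, x_m, y_m; it
    is consulted only for the lone-eating case (rule iii).
    """
    th = thresholds or Thresholds()
    if roost_mask:
        return "none"
    eating = int(stop["n_eating"])
    running = int(stop["n_running"])
    if eating >= th.min_eating_alone:
        return "feeding"
    if eating == 1 and running >= th.min_running_with_one_eating:
        return "feeding"
    if eating == 1 and running == 1:
        return "undecided"
    if eating == 1 and running == 0:
        for other in co_feeding_index:
            if other["animal_id"] == stop["animal_id"]:
                continue
            if other["end"] < stop["start"] or other["start"] > stop["end"]:
                continue
            dist = np.hypot(stop["x_m"] - other["x_m"],
                            stop["y_m"] - other["y_m"])
            if dist <= th.cofeed_radius_m:
                return "feeding"
        return "none"
    return "none"


def resolve_in_roost(stops: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Stop centroid lies within a major-roost site's radius."""
    roosts = sites.loc[sites["kind"] == "roost"]
    flags = np.zeros(len(stops), dtype=bool)
    if not len(roosts) or not len(stops):
        return flags
    sx = stops["x_m"].to_numpy()
    sy = stops["y_m"].to_numpy()
    for _, r in roosts.iterrows():
        flags |= np.hypot(sx - r["x_m"], sy - r["y_m"]) <= r["radius_m"]
    return flags


def classify_stops(stops: pd.DataFrame, sites: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Two-pass classification of all stops.

    Pass 1 applies rules i/ii (and the undecided rule); pass 2 resolves the
    lone-eating stops of rule iii against the pass-1 feeding stops.  The
    result is independent of animal processing order because rule iii only
    ever consults pass-1 classifications.
    """
    th = thresholds or Thresholds()
    out = stops.copy()
    if not len(out):
        out["in_roost"] = pd.Series(dtype=bool)
        out["classification"] = pd.Series(dtype=object)
        return out
    out["in_roost"] = resolve_in_roost(out, sites)

    cls = np.full(len(out), "none", dtype=object)
    eating = out["n_eating"].to_numpy()
    running = out["n_running"].to_numpy()
    roost = out["in_roost"].to_numpy()
    rule1 = eating >= th.min_eating_alone
    rule2 = (eating == 1) & (running >= th.min_running_with_one_eating)
    cls[(rule1 | rule2) & ~roost] = "feeding"
    cls[(eating == 1) & (running == 1) & ~roost] = "undecided"

    pass1 = out.loc[cls == "feeding",
                    ["animal_id", "start", "end", "x_m", "y_m"]]
    index = pass1.to_dict("records")
    lone = np.where((eating == 1) & (running == 0) & ~roost)[0]
    for i in lone:
        cls[i] = classify_stop(out.iloc[i], False, index, th)
    out["classification"] = cls
    return out


def build_feeding_events(classified_stops: pd.DataFrame,
                         sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse feeding-classified stops to at most one event per animal-day."""
    if not len(classified_stops):
        return pd.DataFrame(columns=EVENT_COLUMNS)
    feed = classified_stops.loc[classified_stops["classification"] == "feeding"]
    if not len(feed):
        return pd.DataFrame(columns=EVENT_COLUMNS)
    sfs = sites.loc[sites["kind"] == "sfs"]
    rows = []
    for (aid, date), grp in feed.groupby(["animal_id", "date"]):
        first = grp.sort_values("start").iloc[0]
        at_sfs = False
        if len(sfs):
            at_sfs = bool((np.hypot(sfs["x_m"] - first["x_m"],
                                    sfs["y_m"] - first["y_m"])
                           <= sfs["radius_m"]).any())
        rows.append({"animal_id": aid, "date": pd.Timestamp(date).normalize(),
                     "x_m": first["x_m"], "y_m": first["y_m"],
                     "at_sfs": at_sfs, "fdp": np.nan, "valid": False,
                     "exclusion_reason": "unknown_history"})
    return (pd.DataFrame(rows)
            .sort_values(["animal_id", "date"]).reset_index(drop=True))


def compute_fdp(events: pd.DataFrame, daily: pd.DataFrame,
                classified_stops: pd.DataFrame,
                thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Attach FDP (days) and validity to each feeding event.

    FDP counts the whole non-feeding days between consecutive feeding dates
    of one animal (feeding days themselves are not counted).  An event is
    excluded when its gap contains a missing day or a day with an undecided
    stop, when the animal's history is unknown (first event), or when the
    FDP exceeds ``fdp_cap_days``.
    """
    th = thresholds or Thresholds()
    ev = events.copy()
    if not len(ev):
        return ev
    ev["date"] = pd.to_datetime(ev["date"]).dt.normalize()

    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.normalize()
    covered = {(r.animal_id, r.date) for r in daily.itertuples()
               if not r.missing_day}
    undecided: set = set()
    if len(classified_stops):
        und = classified_stops.loc[
            classified_stops["classification"] == "undecided"]
        undecided = {(r.animal_id, pd.Timestamp(r.date).normalize())
                     for r in und.itertuples()}

    fdp = np.full(len(ev), np.nan)
    valid = np.zeros(len(ev), dtype=bool)
    reason = np.full(len(ev), "unknown_history", dtype=object)
    ev = ev.sort_values(["animal_id", "date"]).reset_index(drop=True)
    for aid, grp in ev.groupby("animal_id"):
        idx = grp.index.to_numpy()
        dates = grp["date"].to_numpy()
        for k in range(1, len(idx)):
            gap = int((dates[k] - dates[k - 1]) / np.timedelta64(1, "D")) - 1
            fdp[idx[k]] = gap
            gap_days = [pd.Timestamp(dates[k - 1]) + pd.Timedelta(days=j)
                        for j in range(1, gap + 1)]
            if any((aid, day) not in covered for day in gap_days):
                reason[idx[k]] = "missing_day_in_gap"
            elif any((aid, day) in undecided for day in gap_days):
                reason[idx[k]] = "undecided_in_gap"
            elif gap > th.fdp_cap_days:
                reason[idx[k]] = "fdp_over_14"
            else:
                reason[idx[k]] = "none"
                valid[idx[k]] = True
    ev["fdp"] = fdp
    ev["valid"] = valid
    ev["exclusion_reason"] = reason
    return ev


def categorize(length: int, thresholds: Thresholds | None = None) -> str:
    th = thresholds or Thresholds()
    if length == 0:
        return "zero"
    if th.short_min <= length <= th.short_max:
        return "short"
    if length >= th.long_min:
        return "long"
    return "mid"


def build_sequences(events: pd.DataFrame, daily: pd.DataFrame,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Long table of FDP-sequence days with daily metrics attached.

    One sequence per valid event: day 0 is the feeding day *opening* the
    sequence (the previous feeding event) and day ``fdp`` is the last
    non-feeding day before the terminal event.
    """
    th = thresholds or Thresholds()
    if not len(events):
        return pd.DataFrame()
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.normalize()
    metric_by_day = daily.set_index(["animal_id", "date"])

    rows = []
    valid = events.loc[events["valid"]]
    for ev in valid.itertuples():
        length = int(ev.fdp)
        open_date = ev.date - pd.Timedelta(days=length + 1)
        event_id = f"{ev.animal_id}:{ev.date.date().isoformat()}"
        seq_rows = []
        ok = True
        for d in range(length + 1):
            key = (ev.animal_id, open_date + pd.Timedelta(days=d))
            if key not in metric_by_day.index:
                logger.warning("sequence %s dropped: no metrics for day %s",
                               event_id, key[1].date())
                ok = False
                break
            met = metric_by_day.loc[key]
            seq_rows.append({
                "animal_id": ev.animal_id, "event_id": event_id,
                "day_index": d, "date": key[1], "length": length,
                "category": categorize(length, th),
                "travel_km": met["travel_km"],
                "max_disp_km": met["max_disp_km"],
                "straightness": met["straightness"],
                "mean_speed": met["mean_speed"],
                "flight_elev_m": met["flight_elev_m"],
                "departure_h": met["departure_h"],
                "active": met["active"],
                "prop_active_flight": met["prop_active_flight"],
            })
        if ok:
            rows.extend(seq_rows)
    return pd.DataFrame(rows)


def fdp_histogram(events: pd.DataFrame,
                  thresholds: Thresholds | None = None):
    """Counts of valid events by FDP 0..cap, plus monthly long-FDP proportions.

    Monthly proportions use the terminal event's calendar month.
    """
    th = thresholds or Thresholds()
    cap = th.fdp_cap_days
    counts = np.zeros(cap + 1, dtype=int)
    monthly_rows = []
    if len(events):
        valid = events.loc[events["valid"]].copy()
        for f in valid["fdp"].astype(int):
            if 0 <= f <= cap:
                counts[f] += 1
        if len(valid):
            valid["month"] = pd.to_datetime(valid["date"]).dt.month
            for month in range(1, 13):
                sub = valid.loc[valid["month"] == month]
                n = len(sub)
                n_long = int((sub["fdp"] >= th.long_min).sum())
                monthly_rows.append({
                    "month": month, "n_events": n, "n_long": n_long,
                    "prop_long": n_long / n if n else np.nan})
    monthly = pd.DataFrame(monthly_rows,
                           columns=["month", "n_events", "n_long", "prop_long"])
    return counts, monthly


def subset_events(events: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Restrict events to those ending at stations (``sfs``) or away from
    them (``occasional``); ``all`` is a no-op."""
    if subset == "all" or not len(events):
        return events
    if subset == "sfs":
        return events.loc[events["at_sfs"]].reset_index(drop=True)
    if subset == "occasional":
        return events.loc[~events["at_sfs"]].reset_index(drop=True)
    raise ValueError(f"unknown subset {subset!r}")
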
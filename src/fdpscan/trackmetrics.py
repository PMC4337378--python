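"""Daily movement metrics and ground-stop detection from GPS fix tables.

All geometry is planar (local metres).  A day is the local calendar date of
the diurnal duty window; per-day operations expect the fixes of a single
animal-day sorted by time.  Conventions follow the tracking protocol this
package models: a fix is *non-static* iff its instantaneous ground speed
exceeds 4 m/s (strict), a day is *active* iff the maximal displacement from
the first fix of the day exceeds 2 km (strict), and a *day-stop* is a run of
fixes within a 400 m radius spanning more than 20 minutes.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .config import BEHAVIOR_LABELS, Thresholds

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "animal_id", "date", "missing_day", "n_fixes", "n_interpolated",
    "active", "departure_h", "departure_censored", "travel_km",
    "max_disp_km", "straightness", "mean_speed", "flight_elev_m",
    "prop_active_flight",
]

STOP_COLUMNS = (
    ["animal_id", "date", "start", "end", "x_m", "y_m", "duration_min",
     "n_fixes", "roost_candidate"] + [f"n_{lab}" for lab in BEHAVIOR_LABELS]
)


def day_schedule(date: dt.date, duty_start: dt.time = dt.time(6, 30),
                 duty_end: dt.time = dt.time(18, 30),
                 interval_min: int = 10) -> pd.DatetimeIndex:
    """The expected fix grid of one duty-cycle day (endpoints inclusive)."""
    start = pd.Timestamp.combine(pd.Timestamp(date), duty_start)
    end = pd.Timestamp.combine(pd.Timestamp(date), duty_end)
    return pd.date_range(start, end, freq=f"{interval_min}min")


# ---------------------------------------------------------------------------
# Per-day primitives (operate on one animal-day of fixes)


def interpolate_missing_fixes(fixes: pd.DataFrame,
                              schedule: pd.DatetimeIndex) -> pd.DataFrame | None:
    """Fill scheduled slots that lack a fix by linear time-interpolation.

    A slot is considered covered when a real fix lies within half an
    interval of it.  Interpolation never extrapolates beyond the first or
    last real fix.  Returns ``None`` (missing day) when fewer than two real
    fixes exist.
    """
    real = fixes.loc[~fixes["interpolated_flag"].astype(bool)]
    if len(real) < 2:
        return None
    t = real["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    if len(schedule) > 1:
        half = (schedule[1] - schedule[0]).value / 2
    else:
        half = 0
    s = schedule.to_numpy().astype(np.int64)
    covered = np.zeros(len(s), dtype=bool)
    idx = np.searchsorted(t, s)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, len(t) - 1)
        covered |= np.abs(t[j] - s) <= half
    need = (~covered) & (s > t[0]) & (s < t[-1])
    if not need.any():
        return fixes.sort_values("timestamp").reset_index(drop=True)
    ts_new = s[need]
    interp = {
        col: np.interp(ts_new, t, real[col].to_numpy())
        for col in ("x_m", "y_m", "altitude_m", "ground_speed_ms")
    }
    filled = pd.DataFrame({
        "animal_id": real["animal_id"].iloc[0],
        "timestamp": pd.to_datetime(ts_new),
        "x_m": interp["x_m"], "y_m": interp["y_m"],
        "altitude_m": interp["altitude_m"],
        "ground_speed_ms": interp["ground_speed_ms"],
        "interpolated_flag": True,
    })
    out = pd.concat([fixes, filled], ignore_index=True)
    return out.sort_values("timestamp").reset_index(drop=True)


def max_displacement(fixes: pd.DataFrame) -> float:
    """Greatest planar distance (km) from the first fix of the day."""
    x = fixes["x_m"].to_numpy()
    y = fixes["y_m"].to_numpy()
    if len(x) == 0:
        return float("nan")
    return float(np.hypot(x - x[0], y - y[0]).max()) / 1000.0


def daily_travel_distance(fixes: pd.DataFrame) -> float:
    """Sum of consecutive-fix segment lengths (km); 0 with fewer than 2 fixes."""
    x = fixes["x_m"].to_numpy()
    y = fixes["y_m"].to_numpy()
    if len(x) < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum()) / 1000.0


def classify_active_day(fixes: pd.DataFrame,
                        activity_radius_m: float = 2000.0) -> bool:
    """Active iff the bird moved strictly more than 2 km from its roost."""
    return max_displacement(fixes) * 1000.0 > activity_radius_m


def straightness(fixes: pd.DataFrame,
                 convention: str = "out_and_back") -> float:
    """Daily path-efficiency ratio in [0, 1].

    ``out_and_back`` (default): 2 * Dmax / L clipped to 1 — exact for a
    round trip that retraces a straight line.  ``to_farthest``: Dmax over
    the path length accumulated up to the farthest fix.
    """
    travel = daily_travel_distance(fixes)
    if travel <= 0:
        return float("nan")
    x = fixes["x_m"].to_numpy()
    y = fixes["y_m"].to_numpy()
    disp = np.hypot(x - x[0], y - y[0])
    far = int(disp.argmax())  # earliest fix on ties
    dmax = disp[far] / 1000.0
    if convention == "to_farthest":
        if far == 0:
            return float("nan")
        upto = float(np.hypot(np.diff(x[:far + 1]), np.diff(y[:far + 1])).sum()) / 1000.0
        return min(1.0, dmax / upto) if upto > 0 else float("nan")
    return min(1.0, 2.0 * dmax / travel)


def roost_departure_time(fixes: pd.DataFrame, sunrise: pd.Timestamp,
                         static_speed_ms: float = 4.0):
    """Hours from sunrise to the first non-static fix.

    Returns ``(offset_hours, censored)``; offset is ``nan`` with a warning
    when an active day has no non-static fix.  The observation is
    left-censored when the very first sample of the day is already
    non-static (the bird left before sampling began).
    """
    speeds = fixes["ground_speed_ms"].to_numpy()
    moving = speeds > static_speed_ms
    if not moving.any():
        logger.warning("active day with no non-static fix: %s %s",
                       fixes["animal_id"].iloc[0], fixes["timestamp"].iloc[0])
        return float("nan"), False
    first = int(np.argmax(moving))
    if first == 0:
        return float("nan"), True
    ts = fixes["timestamp"].iloc[first]
    return (ts - sunrise).total_seconds() / 3600.0, False


def detect_day_stops(fixes: pd.DataFrame, behaviors: pd.DataFrame | None,
                     thresholds: Thresholds | None = None) -> list[dict]:
    """Greedy left-to-right scan for ground stops.

    A stop opens at the first static fix and extends while each subsequent
    fix lies within the stop radius of the running centroid; it is emitted
    when its time span strictly exceeds the minimum duration.  Behaviour
    records falling inside [start, end] are tallied per label.  The last
    emitted stop of the day is tagged as the evening-roost candidate.
    """
    th = thresholds or Thresholds()
    x = fixes["x_m"].to_numpy()
    y = fixes["y_m"].to_numpy()
    v = fixes["ground_speed_ms"].to_numpy()
    ts = fixes["timestamp"].to_numpy()
    n = len(x)
    stops: list[dict] = []
    i = 0
    while i < n:
        if v[i] > th.static_speed_ms:
            i += 1
            continue
        cx, cy, m = x[i], y[i], 1
        j = i + 1
        while j < n:
            if np.hypot(x[j] - cx, y[j] - cy) > th.stop_radius_m:
                break
            cx = (cx * m + x[j]) / (m + 1)
            cy = (cy * m + y[j]) / (m + 1)
            m += 1
            j += 1
        span_min = (ts[j - 1] - ts[i]) / np.timedelta64(60, "s")
        if span_min > th.stop_min_duration_min:
            stops.append({
                "start": pd.Timestamp(ts[i]), "end": pd.Timestamp(ts[j - 1]),
                "x_m": cx, "y_m": cy, "duration_min": float(span_min),
                "n_fixes": m, "roost_candidate": False,
            })
        i = j if j > i + 1 else i + 1
    if stops:
        stops[-1]["roost_candidate"] = True
    for st in stops:
        counts = dict.fromkeys(BEHAVIOR_LABELS, 0)
        if behaviors is not None and len(behaviors):
            sel = behaviors.loc[
                (behaviors["timestamp"] >= st["start"])
                & (behaviors["timestamp"] <= st["end"]), "label"]
            for lab, cnt in sel.value_counts().items():
                if lab in counts:
                    counts[lab] += int(cnt)
        for lab in BEHAVIOR_LABELS:
            st[f"n_{lab}"] = counts[lab]
    return stops


def compute_daily_metrics(fixes: pd.DataFrame, behaviors: pd.DataFrame | None,
                          sunrise: pd.Timestamp,
                          thresholds: Thresholds | None = None) -> dict:
    """All daily movement characteristics for one animal-day (interpolated)."""
    th = thresholds or Thresholds()
    out = {
        "animal_id": fixes["animal_id"].iloc[0] if len(fixes) else None,
        "date": pd.Timestamp(fixes["timestamp"].iloc[0]).normalize()
        if len(fixes) else pd.NaT,
        "missing_day": False,
        "n_fixes": int(len(fixes)),
        "n_interpolated": int(fixes["interpolated_flag"].astype(bool).sum()),
    }
    dmax = max_displacement(fixes)
    travel = daily_travel_distance(fixes)
    active = dmax * 1000.0 > th.activity_radius_m
    out.update(active=active, travel_km=travel, max_disp_km=dmax,
               straightness=straightness(fixes, th.straightness_convention)
               if travel > 0 else float("nan"))
    speeds = fixes["ground_speed_ms"].to_numpy()
    moving = speeds > th.static_speed_ms
    out["mean_speed"] = float(speeds[moving].mean()) if moving.any() else float("nan")
    out["flight_elev_m"] = (float(fixes["altitude_m"].to_numpy()[moving].mean())
                            if moving.any() else float("nan"))
    if active:
        dep, cens = roost_departure_time(fixes, sunrise, th.static_speed_ms)
    else:
        dep, cens = float("nan"), False
    out["departure_h"] = dep
    out["departure_censored"] = cens
    if behaviors is not None and len(behaviors):
        lab = behaviors["label"]
        nf_act = int((lab == "active_flight").sum())
        nf_pas = int((lab == "passive_flight").sum())
        out["prop_active_flight"] = (nf_act / (nf_act + nf_pas)
                                     if nf_act + nf_pas else float("nan"))
    else:
        out["prop_active_flight"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Dataset-level driver


def compute_all_metrics(fixes: pd.DataFrame, behaviors: pd.DataFrame,
                        sunrise: pd.DataFrame,
                        thresholds: Thresholds | None = None,
                        duty_start: dt.time = dt.time(6, 30),
                        duty_end: dt.time = dt.time(18, 30),
                        interval_min: int = 10):
    """Interpolate, measure and scan every animal-day of a fix table.

    Returns ``(daily, stops)`` DataFrames.  Days with fewer than two real
    fixes are emitted as ``missing_day`` rows with no metrics.  Fixes
    outside the duty window are ignored.
    """
    th = thresholds or Thresholds()
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    tod = fixes["timestamp"].dt.time
    fixes = fixes.loc[(tod >= duty_start) & (tod <= duty_end)]
    behaviors = behaviors.copy()
    behaviors["timestamp"] = pd.to_datetime(behaviors["timestamp"])

    sun = sunrise.copy()
    sun["date"] = pd.to_datetime(sun["date"]).dt.normalize()
    sunrise_by_date = {
        row["date"]: row["date"] + pd.Timedelta(str(row["time"]))
        for _, row in sun.iterrows()
    }

    beh_groups = {k: g for k, g in behaviors.groupby(
        ["animal_id", behaviors["timestamp"].dt.normalize()])}

    daily_rows, stop_rows = [], []
    for (aid, date), day_fixes in fixes.groupby(
            ["animal_id", fixes["timestamp"].dt.normalize()]):
        schedule = day_schedule(date.date(), duty_start, duty_end, interval_min)
        interp = interpolate_missing_fixes(
            day_fixes.sort_values("timestamp"), schedule)
        if interp is None:
            daily_rows.append({"animal_id": aid, "date": date,
                               "missing_day": True,
                               "n_fixes": int(len(day_fixes)),
                               "n_interpolated": 0})
            continue
        beh = beh_groups.get((aid, date))
        sr = sunrise_by_date.get(date)
        if sr is None:  # fall back to the protocol default sunrise
            sr = date + pd.Timedelta(hours=5, minutes=42)
        row = compute_daily_metrics(interp, beh, sr, th)
        row["animal_id"], row["date"] = aid, date
        daily_rows.append(row)
        for st in detect_day_stops(interp, beh, th):
            st["animal_id"], st["date"] = aid, date
            stop_rows.append(st)

    daily = pd.DataFrame(daily_rows)
    for col in METRIC_COLUMNS:
        if col not in daily.columns:
            daily[col] = np.nan
    daily = daily[METRIC_COLUMNS].sort_values(
        ["animal_id", "date"]).reset_index(drop=True)
    stops = pd.DataFrame(stop_rows, columns=STOP_COLUMNS)
    if len(stops):
        stops = stops.sort_values(["animal_id", "date", "start"]).reset_index(drop=True)
    return daily, stops
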
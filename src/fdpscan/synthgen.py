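"""Synthetic multi-animal GPS/behaviour biologging generator.

Emulates the measurement design of a GPS/ACC vulture-tracking study: 10-min
fixes on a 12-h diurnal duty cycle with ~10 % dropout, seven-class behaviour
bursts on the same schedule, day-by-day feeding governed by a memoryless
(geometric) food-deprivation process with seasonal modulation, and a
hump-shaped dependence of daily travel effort on days-since-feeding.

The within-day spatial process is an out-and-back S-shaped double arc whose
polyline length equals ``tortuosity`` times twice the maximal displacement,
so the daily straightness measured downstream (2 * Dmax / L) equals
1 / tortuosity by construction.  A truth ledger records the true feeding
days and day-within-deprivation state of every animal-day; the analysis
path never reads it (it exists for recovery tests only).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import BEHAVIOR_LABELS, ConfigError, SimConfig

_FILLER_LABELS = ("standing", "lying", "preening", "passive_flight")
_FILLER_P = (0.45, 0.25, 0.25, 0.05)

FIX_COLUMNS = [
    "animal_id", "timestamp", "x_m", "y_m",
    "altitude_m", "ground_speed_ms", "interpolated_flag",
]
BEHAVIOR_COLUMNS = ["animal_id", "timestamp", "label"]
SITE_COLUMNS = ["site_id", "kind", "x_m", "y_m", "radius_m"]


@dataclass
class TrackDataset:
    """One simulated population: fix, behaviour, site and sunrise tables.

    ``truth`` is the generator's private ledger (true feeding days and
    day-within-FDP state per animal-day); analysis code must not read it.
    """

    fixes: pd.DataFrame
    behaviors: pd.DataFrame
    sites: pd.DataFrame
    sunrise: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# FDP durations


def sample_fdp_durations(n: int, p0: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` food-deprivation periods (whole days, >= 0).

    The per-day feeding probability is memoryless, so durations follow a
    geometric law on {0, 1, 2, ...} with success probability ``p0``: the
    expected fraction of zero-day periods (feeding on consecutive days) is
    ``p0`` and the mean is (1 - p0) / p0.
    """
    if not 0.0 < p0 <= 1.0:
        raise ConfigError(f"p0={p0} outside (0, 1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    return rng.geometric(p0, size=n) - 1


# ---------------------------------------------------------------------------
# Stop behaviour compositions


def emit_stop_behaviors(stop_kind: str, config: SimConfig,
                        rng: np.random.Generator, n_slots: int = 8) -> list[str]:
    """Behaviour-label multiset for one ground stop of ``n_slots`` bursts.

    ``feeding`` stops satisfy rule i (>= 2 eating bursts) or, with
    probability ``config.p_rule2_feeding``, rule ii (a single eating burst
    with >= 2 running bursts).  ``ambiguous`` stops carry exactly one eating
    and one running burst (classified undecided downstream).  ``loafing``
    stops carry no eating at all.  Remaining slots are filled with loafing
    behaviours.  Diagnostic (eating/running) labels come first in the
    returned list.
    """
    if n_slots < 2:
        n_slots = 2
    if stop_kind == "feeding":
        if rng.random() < config.p_rule2_feeding:
            eating = 1
            running = 2 + rng.poisson(0.5)
        else:
            eating = 2 + rng.poisson(max(0.0, config.eating_burst_rate - 2.0))
            running = rng.poisson(config.running_burst_rate)
            # keep clear of the undecided composition (1 eating, 1 running)
            eating = max(eating, 2)
        if eating + running > n_slots:
            running = max(0, n_slots - eating) if eating >= 2 else running
            eating = min(eating, n_slots if eating >= 2 else eating)
            if eating + running > n_slots:  # still too many: shrink to rule i core
                eating, running = min(eating, max(2, n_slots)), 0
    elif stop_kind == "ambiguous":
        eating, running = 1, 1
    elif stop_kind == "loafing":
        eating, running = 0, 0
    else:
        raise ConfigError(f"unknown stop kind {stop_kind!r}")
    diag = ["eating"] * eating + ["running"] * running
    n_fill = max(0, n_slots - len(diag))
    fill = list(rng.choice(_FILLER_LABELS, size=n_fill, p=_FILLER_P))
    return diag + fill


# ---------------------------------------------------------------------------
# Path geometry


@lru_cache(maxsize=256)
def _arc_angle(tau_mdeg: int, n_seg: int) -> float:
    """Central angle of a circular arc sampled by ``n_seg`` chords whose
    polyline is ``tau`` times the straight chord (tau passed in milli-units
    for cache hashing)."""
    tau = tau_mdeg / 1000.0
    if tau <= 1.0 or n_seg < 2:
        return 0.0

    def ratio(theta: float) -> float:
        return n_seg * np.sin(theta / (2 * n_seg)) / np.sin(theta / 2) - tau

    return brentq(ratio, 1e-6, 2 * np.pi - 1e-6)


def _arc_points(start: np.ndarray, end: np.ndarray, n_seg: int,
                tau: float, side: float) -> np.ndarray:
    """``n_seg`` points along a circular arc from start (excl.) to end
    (incl.) whose sampled polyline length is ``tau`` times |end - start|."""
    chord = end - start
    d = float(np.hypot(*chord))
    theta = _arc_angle(int(round(tau * 1000)), n_seg)
    if theta <= 0 or d == 0:
        fr = np.arange(1, n_seg + 1)[:, None] / n_seg
        return start + fr * chord
    radius = d / (2 * np.sin(theta / 2))
    u = chord / d
    v = np.array([-u[1], u[0]]) * side
    # circle centre in the (u, v) chord frame
    centre = start + u * (d / 2) - v * (radius * np.cos(theta / 2))
    a0 = np.arctan2(*((start - centre)[::-1]))
    a1 = np.arctan2(*((end - centre)[::-1]))
    sweep = (a1 - a0) % (2 * np.pi)
    if not np.isclose(sweep, theta, atol=1e-6):
        sweep = sweep - 2 * np.pi  # go the other way around
    angles = a0 + sweep * np.arange(1, n_seg + 1) / n_seg
    return centre + radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _outbound_path(roost: np.ndarray, far: np.ndarray, n_half: int,
                   tau: float, rng: np.random.Generator) -> np.ndarray:
    """S-shaped double arc roost -> far with polyline length tau * |far - roost|.

    Two opposite-bulge arcs of equal chord keep the far point the most
    distant vertex from the roost, so 2 * Dmax / L = 1 / tau exactly.
    """
    mid = (roost + far) / 2
    side = 1.0 if rng.random() < 0.5 else -1.0
    first = _arc_points(roost, mid, n_half, tau, side)
    second = _arc_points(mid, far, n_half, tau, -side)
    return np.vstack([first, second])


# ---------------------------------------------------------------------------
# One animal-day

_ROOST, _FLIGHT, _STOP = 0, 1, 2


def simulate_vulture_day(day_state: dict, config: SimConfig,
                         rng: np.random.Generator) -> dict:
    """Simulate one animal-day; returns slot-level arrays and stop truth.

    ``day_state`` carries: date, day_in_fdp, active, feeding, roost (xy),
    sfs_xy (array of station coordinates), sfs_ids.
    """
    if day_state["day_in_fdp"] < 0:
        raise ConfigError("day_in_fdp must be >= 0")
    n = config.n_slots
    pos = np.empty((n, 2))
    kind = np.full(n, _ROOST, dtype=np.int8)
    stop_of_slot = np.full(n, -1, dtype=np.int32)
    roost = np.asarray(day_state["roost"], dtype=float)
    stops: list[dict] = []  # kind, slot range, xy

    d = day_state["day_in_fdp"]
    feeding = day_state["feeding"]
    active = day_state["active"]
    censored = False

    if not active:
        pos[:] = roost
        if feeding:
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(1100.0, 1600.0)
            sxy = roost + dist * np.array([np.cos(ang), np.sin(ang)])
            s0, dur = n // 2 - 6, 12
            pos[s0:s0 + dur] = sxy
            kind[s0:s0 + dur] = _STOP
            stop_of_slot[s0:s0 + dur] = 0
            stops.append({"kind": "feeding", "start": s0, "end": s0 + dur - 1,
                          "xy": sxy})
    else:
        td_km = config.hump_mean_km(d) * float(
            np.exp(rng.normal(-config.daily_cv ** 2 / 2, config.daily_cv)))
        td_km = max(20.0, td_km)
        disp = td_km * 1000.0 / (2.0 * config.tortuosity)
        at_sfs = False
        if feeding and len(day_state["sfs_xy"]) and rng.random() < config.p_feed_at_sfs:
            sfs = day_state["sfs_xy"]
            dists = np.hypot(sfs[:, 0] - roost[0], sfs[:, 1] - roost[1])
            # stations inside the activity radius would blur the active/
            # inactive dichotomy; keep feeding destinations clearly away
            cand = np.where(dists > 2500.0)[0]
            if len(cand):
                j = cand[np.argmin(np.abs(dists[cand] - disp))]
                jitter = rng.normal(0, config.sfs_radius_m / 6, size=2)
                far = sfs[j] + jitter
                disp = float(np.hypot(*(far - roost)))
                at_sfs = True
            else:
                far = None
        else:
            far = None
        if far is None:
            ang = rng.uniform(0, 2 * np.pi)
            far = roost + disp * np.array([np.cos(ang), np.sin(ang)])

        # departure time -> first flight slot
        offset_h = max(0.0, rng.normal(config.departure_mean_h, config.departure_sd_h))
        sunrise_min = config.sunrise.hour * 60 + config.sunrise.minute
        dep_min = sunrise_min + offset_h * 60.0
        duty0 = config.duty_start.hour * 60 + config.duty_start.minute
        dep_slot = int(np.ceil(max(0.0, dep_min - duty0) / config.fix_interval_min))
        censored = dep_min <= duty0
        dep_slot = min(dep_slot, n - 12)

        # slot budget: out + stops + back must fit the remaining duty window
        stop_plan: list[tuple[str, int]] = []
        if feeding:
            stop_plan.append(("feeding", int(rng.integers(10, 19))))
        n_extra = min(3, rng.poisson(max(0.0, config.stop_rate - 1.0)))
        for _ in range(n_extra):
            if rng.random() < config.p_ambiguous_stop:
                stop_plan.append(("ambiguous", int(rng.integers(6, 9))))
            else:
                stop_plan.append(("loafing", int(rng.integers(2, 7))))
        avail = n - dep_slot
        leg_m = config.tortuosity * disp
        n_half = max(2, int(round(leg_m / (600.0 * config.speed_mean_ms) / 2)))
        while stop_plan and 4 * 2 + sum(s for _, s in stop_plan) > avail - 1:
            stop_plan.pop()  # rare: shed stops on very late departures
        max_half = max(2, (avail - 1 - sum(s for _, s in stop_plan)) // 4)
        n_half = min(n_half, max_half)
        n_leg = 2 * n_half

        out_pts = _outbound_path(roost, far, n_half, config.tortuosity, rng)
        # pauses at interior outbound vertices; the feeding stop sits at the
        # far point itself (the carcass is the destination)
        interior = list(range(0, n_leg - 1))
        rng.shuffle(interior)
        slot_seq: list[tuple[float, float, int, int]] = []  # x, y, kind, stop_id
        stop_at_vertex: dict[int, list[int]] = {}
        sid = 0
        for skind, sdur in stop_plan:
            if skind == "feeding":
                vtx = n_leg - 1
            else:
                if not interior:
                    continue
                vtx = interior.pop()
            stop_at_vertex.setdefault(vtx, []).append(sid)
            stops.append({"kind": skind, "dur": sdur, "xy": out_pts[vtx],
                          "at_sfs": at_sfs if skind == "feeding" else False})
            sid += 1

        for i in range(n_leg):
            slot_seq.append((out_pts[i, 0], out_pts[i, 1], _FLIGHT, -1))
            for s in stop_at_vertex.get(i, []):
                st = stops[s]
                st["start"] = dep_slot + len(slot_seq)
                for _ in range(st["dur"]):
                    slot_seq.append((st["xy"][0], st["xy"][1], _STOP, s))
                st["end"] = dep_slot + len(slot_seq) - 1
        for i in range(n_leg - 2, -1, -1):  # retrace home
            slot_seq.append((out_pts[i, 0], out_pts[i, 1], _FLIGHT, -1))
        slot_seq.append((roost[0], roost[1], _FLIGHT, -1))

        pos[:dep_slot] = roost
        m = min(len(slot_seq), n - dep_slot)
        arr = np.array([s[:2] for s in slot_seq[:m]])
        pos[dep_slot:dep_slot + m] = arr
        kind[dep_slot:dep_slot + m] = [s[2] for s in slot_seq[:m]]
        stop_of_slot[dep_slot:dep_slot + m] = [s[3] for s in slot_seq[:m]]
        pos[dep_slot + m:] = roost
        for st in stops:
            st.setdefault("start", -1)

    # jitter, speeds, altitudes
    static = kind != _FLIGHT
    jit = rng.normal(0, 1.0, size=(n, 2))
    jscale = np.where(kind == _ROOST, config.roost_jitter_m, config.stop_jitter_m)
    pos = pos + jit * np.where(static, jscale, 0.0)[:, None]

    speed = np.empty(n)
    speed[static] = rng.uniform(0.0, 1.2, size=int(static.sum()))
    if (~static).any():
        idx = np.where(~static)[0]
        prev = np.maximum(idx - 1, 0)
        seg = np.hypot(pos[idx, 0] - pos[prev, 0], pos[idx, 1] - pos[prev, 1])
        speed[idx] = np.maximum(4.5, seg / (config.fix_interval_min * 60.0))

    alt = np.full(n, config.ground_altitude_m) + rng.normal(0, 3.0, size=n)
    if (~static).any():
        z = (d - config.hump_peak_day) / config.hump_peak_day
        elev = config.elevation_base_m + config.elevation_gain_m * max(0.0, 1 - z * z)
        alt[~static] = elev + rng.normal(0, config.elevation_sd_m,
                                         size=int((~static).sum()))

    # behaviour labels per slot
    labels = np.empty(n, dtype=object)
    guaranteed = np.zeros(n, dtype=bool)
    n_static = int(static.sum())
    labels[static] = rng.choice(("standing", "lying", "preening"), size=n_static,
                                p=(0.5, 0.25, 0.25))
    if (~static).any():
        flap = rng.random(int((~static).sum())) < config.p_flapping
        labels[~static] = np.where(flap, "active_flight", "passive_flight")
    for s, st in enumerate(stops):
        if st.get("start", -1) < 0 or st["kind"] == "loafing":
            continue
        slots = np.where(stop_of_slot == s)[0]
        if len(slots) < 4:
            continue
        interior_slots = slots[2:-2] if len(slots) >= 6 else slots[1:-1]
        comp = emit_stop_behaviors(st["kind"], config, rng,
                                   n_slots=len(interior_slots))
        n_diag = sum(1 for c in comp if c in ("eating", "running"))
        for k, lab in enumerate(comp[:len(interior_slots)]):
            labels[interior_slots[k]] = lab
            if k < n_diag:
                guaranteed[interior_slots[k]] = True

    keep_fix = rng.random(n) >= config.p_missing_fix
    if keep_fix.sum() < 2:
        keep_fix[:2] = True
    keep_beh = (rng.random(n) >= config.p_missing_fix) | guaranteed

    return {
        "pos": pos, "speed": speed, "alt": alt,
        "keep_fix": keep_fix, "keep_beh": keep_beh, "labels": labels,
        "stops": stops, "censored_departure": censored,
    }


# ---------------------------------------------------------------------------
# Population


def _make_sites(config: SimConfig, rng: np.random.Generator):
    half = config.region_km * 500.0  # km -> m, half-extent
    sfs_xy = rng.uniform(-half, half, size=(config.n_sfs, 2))
    roost_xy = rng.uniform(-half * 0.8, half * 0.8, size=(config.n_vultures, 2))
    rows = []
    for i, (x, y) in enumerate(sfs_xy):
        rows.append((f"sfs{i:02d}", "sfs", x, y, config.sfs_radius_m))
    for i, (x, y) in enumerate(roost_xy):
        rows.append((f"roost{i:02d}", "roost", x, y, config.roost_radius_m))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return sites, sfs_xy, roost_xy


def simulate_population(config: SimConfig) -> TrackDataset:
    """Simulate the whole population; deterministic given ``config.seed``."""
    if config.n_days < 2:
        raise ConfigError("n_days must be >= 2")
    root = np.random.SeedSequence(config.seed)
    site_ss, *animal_ss = root.spawn(config.n_vultures + 1)
    sites, sfs_xy, roost_xy = _make_sites(config, np.random.default_rng(site_ss))

    slot_td = [pd.Timedelta(minutes=config.duty_start.hour * 60
                            + config.duty_start.minute
                            + i * config.fix_interval_min)
               for i in range(config.n_slots)]
    slot_td = pd.to_timedelta(slot_td)

    fix_parts, beh_parts, truth_rows = [], [], []
    dates = [config.start_date + dt.timedelta(days=i) for i in range(config.n_days)]

    for a in range(config.n_vultures):
        rng = np.random.default_rng(animal_ss[a])
        aid = f"v{a:02d}"
        roost = roost_xy[a]
        d_in_fdp = 0
        for i, date in enumerate(dates):
            month = date.month
            feeding = True if i == 0 else rng.random() < config.feeding_prob(month)
            d_in_fdp = 0 if feeding else d_in_fdp + 1
            active = rng.random() < config.p_active_day
            day = simulate_vulture_day(
                {"date": date, "day_in_fdp": d_in_fdp, "feeding": feeding,
                 "active": active, "roost": roost, "sfs_xy": sfs_xy},
                config, rng)
            base = pd.Timestamp(date)
            ts = base + slot_td
            kf = day["keep_fix"]
            fix_parts.append(pd.DataFrame({
                "animal_id": aid, "timestamp": ts[kf],
                "x_m": day["pos"][kf, 0], "y_m": day["pos"][kf, 1],
                "altitude_m": day["alt"][kf], "ground_speed_ms": day["speed"][kf],
                "interpolated_flag": False,
            }))
            kb = day["keep_beh"]
            beh_parts.append(pd.DataFrame({
                "animal_id": aid, "timestamp": ts[kb],
                "label": day["labels"][kb].astype(str),
            }))
            truth_rows.append((aid, date, month, d_in_fdp, feeding, active,
                               any(s["kind"] == "feeding" and s.get("at_sfs", False)
                                   for s in day["stops"]),
                               day["censored_departure"]))

    fixes = pd.concat(fix_parts, ignore_index=True)
    behaviors = pd.concat(beh_parts, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=[
        "animal_id", "date", "month", "day_in_fdp", "feeding", "active",
        "at_sfs", "censored_departure"])
    truth["date"] = pd.to_datetime(truth["date"])
    sunrise = pd.DataFrame({
        "date": pd.to_datetime(dates),
        "time": [config.sunrise.isoformat() for _ in dates],
    })
    return TrackDataset(fixes=fixes, behaviors=behaviors, sites=sites,
                        sunrise=sunrise, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Writers


def write_dataset(ds: TrackDataset, out_dir: str | Path,
                  include_truth: bool = False) -> dict:
    """Write the dataset's CSV tables; truth stays private unless asked."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("fixes", ds.fixes), ("behaviors", ds.behaviors),
                        ("sites", ds.sites), ("sunrise", ds.sunrise)):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    if include_truth:
        p = out / "truth.csv"
        ds.truth.to_csv(p, index=False)
        paths["truth"] = str(p)
    return paths
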
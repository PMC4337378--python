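"""Readers and writers for the pipeline's CSV tables.

Schemas (headers exact, timestamps ISO-8601):

fixes      animal_id, timestamp, x_m, y_m, altitude_m, ground_speed_ms,
           interpolated_flag  (or lon/lat instead of x_m/y_m — converted to
           local planar metres on read)
behaviors  animal_id, timestamp, label
sites      site_id, kind (sfs|roost), x_m, y_m, radius_m
sunrise    date, time

Geographic input is projected with a local equirectangular approximation
about the dataset centroid; at the ~100 km extent this package targets the
length distortion is below 0.1 %.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import BEHAVIOR_LABELS

EARTH_RADIUS_M = 6_371_000.0


class LoadError(ValueError):
    """A table failed validation on read."""


def lonlat_to_planar(lon, lat, lon0: float | None = None,
                     lat0: float | None = None):
    """Local equirectangular projection to metres about (lon0, lat0)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0 = float(np.mean(lon)) if lon0 is None else lon0
    lat0 = float(np.mean(lat)) if lat0 is None else lat0
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")


def _parse_timestamps(df: pd.DataFrame, path) -> pd.Series:
    try:
        return pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise LoadError(f"{path}: unparseable timestamp ({exc})") from exc


def read_fix_table(path: str | Path) -> pd.DataFrame:
    """Load, validate and planarise a GPS-fix table."""
    df = pd.read_csv(path)
    _require(df, ["animal_id", "timestamp"], path)
    df["timestamp"] = _parse_timestamps(df, path)
    if {"lon", "lat"}.issubset(df.columns) and "x_m" not in df.columns:
        df["x_m"], df["y_m"] = lonlat_to_planar(df["lon"], df["lat"])
    _require(df, ["x_m", "y_m", "altitude_m", "ground_speed_ms"], path)
    if "interpolated_flag" not in df.columns:
        df["interpolated_flag"] = False
    if (df["ground_speed_ms"] < 0).any():
        row = int(df.index[df["ground_speed_ms"] < 0][0])
        raise LoadError(f"{path}: negative ground speed at row {row}")
    df = df.reset_index(drop=True)
    for aid, grp in df.groupby("animal_id"):
        t = grp["timestamp"].to_numpy()
        bad = np.where(np.diff(t) <= np.timedelta64(0, "s"))[0]
        if len(bad):
            row = int(grp.index[bad[0] + 1])
            raise LoadError(
                f"{path}: non-increasing timestamps for animal {aid} "
                f"at row {row}")
    return df


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["animal_id", "timestamp", "label"], path)
    df["timestamp"] = _parse_timestamps(df, path)
    unknown = set(df["label"].unique()) - set(BEHAVIOR_LABELS)
    if unknown:
        raise LoadError(f"{path}: unknown behaviour labels {sorted(unknown)}")
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "kind", "x_m", "y_m", "radius_m"], path)
    bad = set(df["kind"].unique()) - {"sfs", "roost"}
    if bad:
        raise LoadError(f"{path}: unknown site kinds {sorted(bad)}")
    if (df["radius_m"] <= 0).any():
        raise LoadError(f"{path}: non-positive site radius")
    return df.reset_index(drop=True)


def read_sunrise_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["date", "time"], path)
    df["date"] = pd.to_datetime(df["date"])
    return df.reset_index(drop=True)
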
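import numpy as np
import pandas as pd
import pytest

from fdpscan import SimConfig, simulate_population
from fdpscan.trackmetrics import compute_all_metrics


def make_day_fixes(points, speeds=None, start="2010-03-01 06:30",
                   step_min=10, animal="a", alts=None, interpolated=None):
    """One animal-day of fixes from a list of (x, y) metre coordinates."""
    n = len(points)
    ts = pd.date_range(start, periods=n, freq=f"{step_min}min")
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame({
        "animal_id": animal,
        "timestamp": ts,
        "x_m": pts[:, 0],
        "y_m": pts[:, 1],
        "altitude_m": np.asarray(alts, dtype=float) if alts is not None
        else np.full(n, 400.0),
        "ground_speed_ms": np.asarray(speeds, dtype=float) if speeds is not None
        else np.zeros(n),
        "interpolated_flag": np.asarray(interpolated, dtype=bool)
        if interpolated is not None else np.zeros(n, dtype=bool),
    })


@pytest.fixture(scope="session")
def small_dataset():
    """A small paper-default population shared across the suite."""
    return simulate_population(SimConfig(n_vultures=4, n_days=60, seed=3))


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    ds = small_dataset
    daily, stops = compute_all_metrics(ds.fixes, ds.behaviors, ds.sunrise)
    return daily, stops
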
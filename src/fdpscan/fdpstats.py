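"""Statistical analysis of movement responses to food deprivation.

The response of each daily movement characteristic Y to days-since-feeding
X is summarised by per-animal day means (each animal contributes one mean
per day index, avoiding pseudo-replication), then compared across three
nested candidate models fit by ordinary least squares:

    no effect      Y = C
    linear         Y = b X + a
    hump-shaped    Y = a X^2 + b X + c

ranked by AICc with k counting the residual variance (k = 2, 3, 4).  The
module also provides the hungry-vs-satiated paired contrast (day before vs
day after a feeding event) with Benjamini–Yekutieli FDR control, a balanced
two-way repeated-measures ANOVA contrasting short and long deprivation
sequences over days 1–4, and the negative-exponential fit to the FDP
histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Thresholds

SEQUENCE_METRICS = ["travel_km", "max_disp_km", "flight_elev_m",
                    "straightness", "mean_speed", "departure_h",
                    "active", "prop_active_flight"]

_RSS_FLOOR = 1e-12


@dataclass
class ModelFitResult:
    """One candidate response model fit to the day-mean observations."""

    model: str                      # constant | linear | quadratic
    coefficients: tuple             # highest order first (numpy polyfit order)
    rss: float
    n: int
    k: int
    aicc: float
    delta: float = float("nan")
    selected: bool = False
    admissible: bool = True

    @property
    def vertex(self) -> float:
        """Stationary point -b/(2a) of the quadratic; nan otherwise."""
        if self.model != "quadratic" or self.coefficients[0] == 0:
            return float("nan")
        a, b, _ = self.coefficients
        return -b / (2 * a)


@dataclass
class AnovaTable:
    """Balanced two-way repeated-measures ANOVA decomposition."""

    effects: pd.DataFrame           # rows: subject, type, day, type_x_day, residual
    degenerate: bool = False
    n_subjects: int = 0
    metric: str = ""


# ---------------------------------------------------------------------------
# Day means


def per_vulture_day_means(sequences: pd.DataFrame, metric: str,
                          max_fdp: int = 10):
    """Animal x day-index table of metric means over FDP sequences.

    Sequences longer than ``max_fdp`` days are excluded (insufficient
    replication at long deprivation).  Cell (v, d) averages the metric on
    day d over all of v's retained sequences reaching that day.  Also
    returns the per-day grand mean of the animal means and the
    between-animal standard error (the error bars of the day-profile plot).
    """
    if metric not in sequences.columns:
        raise ValueError(f"unknown metric {metric!r}")
    sub = sequences.loc[sequences["length"] <= max_fdp,
                        ["animal_id", "day_index", metric]].copy()
    sub[metric] = pd.to_numeric(sub[metric].astype(float))
    cells = (sub.dropna(subset=[metric])
             .groupby(["animal_id", "day_index"])[metric].mean()
             .unstack("day_index"))
    grand = cells.mean(axis=0)
    n = cells.notna().sum(axis=0)
    se = cells.std(axis=0, ddof=1) / np.sqrt(n)
    summary = pd.DataFrame({"day_index": grand.index, "mean": grand.values,
                            "se": se.values, "n_animals": n.values})
    return cells, summary


# ---------------------------------------------------------------------------
# Model selection


def aicc(rss: float, n: int, k: int) -> float:
    """AICc for a least-squares fit; k includes the residual variance."""
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} (need n > k + 1)")
    return (n * math.log(max(rss, _RSS_FLOOR) / n)
            + 2 * k + 2 * k * (k + 1) / (n - k - 1))


_MODELS = (("constant", 0, 2), ("linear", 1, 3), ("quadratic", 2, 4))


def fit_response_models(day_means, grand_means: bool = False) -> list[ModelFitResult]:
    """Fit and rank the three candidate response models.

    ``day_means`` is the animal x day cell table from
    :func:`per_vulture_day_means` (or any DataFrame shaped that way).  By
    default every non-empty animal-day cell is one observation, weighting
    animals equally; with ``grand_means=True`` the per-day grand means are
    fit instead.  The minimum-AICc admissible model is flagged selected,
    with ties (delta < 1e-9) resolved toward fewer parameters.
    """
    if isinstance(day_means, pd.DataFrame):
        if grand_means:
            ser = day_means.mean(axis=0)
            x = ser.index.to_numpy(dtype=float)
            y = ser.to_numpy(dtype=float)
        else:
            stacked = day_means.stack()
            x = stacked.index.get_level_values(-1).to_numpy(dtype=float)
            y = stacked.to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in day_means)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct day indices")

    results = []
    for name, deg, k in _MODELS:
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        rss = float(resid @ resid)
        n = len(y)
        if n <= k + 1:
            results.append(ModelFitResult(name, tuple(coef), rss, n, k,
                                          float("inf"), admissible=False))
        else:
            results.append(ModelFitResult(name, tuple(coef), rss, n, k,
                                          aicc(rss, n, k)))
    admissible = [r for r in results if r.admissible]
    if not admissible:
        raise ValueError("no admissible model (too few observations)")
    best = min(admissible, key=lambda r: (r.aicc, r.k))
    tied = [r for r in admissible if abs(r.aicc - best.aicc) < 1e-9]
    best = min(tied, key=lambda r: r.k)
    for r in results:
        r.delta = r.aicc - best.aicc
        r.selected = r is best
    return results


def selected_model(results: list[ModelFitResult]) -> ModelFitResult:
    return next(r for r in results if r.selected)


# ---------------------------------------------------------------------------
# Multiple comparisons


def benjamini_yekutieli(p_values, alpha: float = 0.05) -> np.ndarray:
    """Indices rejected by the Benjamini–Yekutieli step-up FDR procedure.

    Valid under arbitrary dependence; the i-th ordered p-value is compared
    with i * alpha / (m * c(m)), c(m) the harmonic sum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_by")
    return np.where(reject)[0]


# ---------------------------------------------------------------------------
# Hungry vs satiated contrast


def hungry_vs_satiated(daily: pd.DataFrame, events: pd.DataFrame,
                       metrics: list[str] | None = None,
                       alpha: float = 0.05, test: str = "t",
                       n_permutations: int = 10000,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Paired day-before vs day-after contrast around feeding events.

    For each event with both flanking days tracked and themselves
    non-feeding, the flanking metric values enter that animal's before/after
    means; the paired test (paired t by default, ``test='permutation'`` for
    a sign-permutation test) runs across animals, and significance is
    BY-adjusted across the metric family.
    """
    metrics = metrics or SEQUENCE_METRICS
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.normalize()
    met = daily.set_index(["animal_id", "date"])
    feeding_days = {(r.animal_id, r.date) for r in events.itertuples()}

    pairs: dict[str, dict[str, list]] = {
        m: {"animal": [], "before": [], "after": []} for m in metrics}
    for ev in events.itertuples():
        before_key = (ev.animal_id, ev.date - pd.Timedelta(days=1))
        after_key = (ev.animal_id, ev.date + pd.Timedelta(days=1))
        if before_key in feeding_days or after_key in feeding_days:
            continue
        if before_key not in met.index or after_key not in met.index:
            continue
        b_row, a_row = met.loc[before_key], met.loc[after_key]
        if bool(b_row.get("missing_day", False)) or bool(a_row.get("missing_day", False)):
            continue
        for m in metrics:
            b, a = float(b_row[m]), float(a_row[m])
            if np.isfinite(b) and np.isfinite(a):
                pairs[m]["animal"].append(ev.animal_id)
                pairs[m]["before"].append(b)
                pairs[m]["after"].append(a)

    rows = []
    for m in metrics:
        df = pd.DataFrame(pairs[m])
        if not len(df):
            rows.append({"metric": m, "n_animals": 0})
            continue
        per = df.groupby("animal")[["before", "after"]].mean()
        n = len(per)
        if n < 3:
            rows.append({"metric": m, "n_animals": n})
            continue
        diff = per["before"].to_numpy() - per["after"].to_numpy()
        if test == "permutation":
            rng = rng or np.random.default_rng(0)
            obs = abs(diff.mean())
            signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diff)))
            null = np.abs((signs * diff).mean(axis=1))
            p = float((np.sum(null >= obs - 1e-15) + 1) / (n_permutations + 1))
            stat = obs
        else:
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_rel(per["before"], per["after"])
        rows.append({"metric": m, "n_animals": n,
                     "mean_before": float(per["before"].mean()),
                     "mean_after": float(per["after"].mean()),
                     "direction": "hungry_higher" if diff.mean() > 0
                     else ("satiated_higher" if diff.mean() < 0 else "equal"),
                     "statistic": float(stat), "p": float(p)})
    table = pd.DataFrame(rows)
    table["significant"] = False
    tested = table.dropna(subset=["p"]) if "p" in table else table.iloc[0:0]
    if len(tested):
        rej = benjamini_yekutieli(tested["p"].to_numpy(), alpha=alpha)
        table.loc[tested.index[rej], "significant"] = True
    return table


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (short vs long sequences, days 1..4)


def rm_anova_short_long(sequences: pd.DataFrame, metric: str,
                        days: tuple = (1, 2, 3, 4), min_sequences: int = 3,
                        thresholds: Thresholds | None = None) -> AnovaTable:
    """Balanced two-way within-subject ANOVA: sequence type x day.

    Subjects are animals with at least ``min_sequences`` long sequences and
    ``min_sequences`` sequences of exactly the short upper-bound length
    (4 days), guaranteeing complete cells.  Cell values are the subject's
    mean metric on each day 1–4 of each sequence type; the classical
    sums-of-squares decomposition (subject, type, day, type x day, pooled
    residual) is reported with a degenerate flag when the residual vanishes.
    """
    th = thresholds or Thresholds()
    days = tuple(days)
    seq = sequences.copy()
    seq[metric] = pd.to_numeric(seq[metric].astype(float))

    lengths = seq.groupby(["animal_id", "event_id"])["length"].first()
    n_long = lengths[lengths >= th.long_min].groupby("animal_id").size()
    n_short4 = lengths[lengths == th.short_max].groupby("animal_id").size()
    subjects = sorted(set(n_long[n_long >= min_sequences].index)
                      & set(n_short4[n_short4 >= min_sequences].index))
    if not subjects:
        raise ValueError("no subject satisfies the sequence-count inclusion rule")

    cells = np.full((len(subjects), 2, len(days)), np.nan)
    for si, aid in enumerate(subjects):
        sub = seq.loc[(seq["animal_id"] == aid)
                      & seq["day_index"].isin(days)]
        short = sub.loc[sub["length"] == th.short_max]
        long_ = sub.loc[sub["length"] >= th.long_min]
        for ti, grp in enumerate((short, long_)):
            means = grp.groupby("day_index")[metric].mean()
            for di, d in enumerate(days):
                if d in means.index:
                    cells[si, ti, di] = means[d]
    if np.isnan(cells).any():
        keep = ~np.isnan(cells).any(axis=(1, 2))
        cells = cells[keep]
        subjects = [s for s, k in zip(subjects, keep) if k]
    if not len(cells):
        raise ValueError("no subject has complete type x day cells")
    table = anova_decompose(cells)
    table.metric = metric
    return table


def anova_decompose(cells) -> AnovaTable:
    """Classical balanced SS decomposition of a subject x type x day array.

    Effects: subject, type, day, type x day, plus a single pooled residual
    stratum (all subject-by-effect interactions).  Component sums of squares
    add to the total on balanced data.
    """
    cells = np.asarray(cells, dtype=float)
    s, t, d = cells.shape
    grand = cells.mean()
    ss_total = float(((cells - grand) ** 2).sum())
    subj_m = cells.mean(axis=(1, 2))
    type_m = cells.mean(axis=(0, 2))
    day_m = cells.mean(axis=(0, 1))
    ss_subject = float(t * d * ((subj_m - grand) ** 2).sum())
    ss_type = float(s * d * ((type_m - grand) ** 2).sum())
    ss_day = float(s * t * ((day_m - grand) ** 2).sum())
    td_m = cells.mean(axis=0)
    inter = td_m - type_m[:, None] - day_m[None, :] + grand
    ss_inter = float(s * (inter ** 2).sum())
    ss_resid = max(ss_total - ss_subject - ss_type - ss_day - ss_inter, 0.0)

    df_subject, df_type, df_day = s - 1, t - 1, d - 1
    df_inter = df_type * df_day
    df_resid = (s * t * d - 1) - df_subject - df_type - df_day - df_inter
    degenerate = ss_resid <= 1e-12 * max(ss_total, 1.0) or df_resid <= 0
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows = []
    for name, ss, dfree in (("subject", ss_subject, df_subject),
                            ("type", ss_type, df_type),
                            ("day", ss_day, df_day),
                            ("type_x_day", ss_inter, df_inter)):
        ms = ss / dfree if dfree > 0 else np.nan
        if degenerate or not np.isfinite(ms_resid) or ms_resid == 0:
            f, p = np.nan, np.nan
        else:
            f = ms / ms_resid
            p = float(stats.f.sf(f, dfree, df_resid))
        rows.append({"effect": name, "ss": ss, "df": dfree, "ms": ms,
                     "F": f, "p": p})
    rows.append({"effect": "residual", "ss": ss_resid, "df": df_resid,
                 "ms": ms_resid, "F": np.nan, "p": np.nan})
    rows.append({"effect": "total", "ss": ss_total, "df": s * t * d - 1,
                 "ms": np.nan, "F": np.nan, "p": np.nan})
    return AnovaTable(effects=pd.DataFrame(rows), degenerate=degenerate,
                      n_subjects=s)


# ---------------------------------------------------------------------------
# FDP distribution fit


def fit_exponential_fdp(counts) -> tuple[float, float, float]:
    """Fit Y = A exp(-b x) to a deprivation-period histogram.

    Least squares of log counts on x over nonzero bins; R^2 is computed on
    the count scale against the fitted curve.  Returns (A, b, r_squared).
    """
    c = np.asarray(counts, dtype=float)
    x = np.arange(len(c), dtype=float)
    nz = c > 0
    if nz.sum() < 3:
        raise ValueError("need at least three nonzero bins")
    slope, intercept = np.polyfit(x[nz], np.log(c[nz]), 1)
    amplitude = float(np.exp(intercept))
    rate = float(-slope)
    fitted = amplitude * np.exp(-rate * x[nz])
    ss_res = float(((c[nz] - fitted) ** 2).sum())
    ss_tot = float(((c[nz] - c[nz].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return amplitude, rate, r2
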
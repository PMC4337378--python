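"""End-to-end pipeline: simulate (optional) -> metrics -> feeding/FDP -> analysis.

Every run writes its artifacts (CSV tables, a machine-readable
``report.json``, a human-readable ``report.md`` and a ``manifest.json``
carrying the config hash and seed) into one output directory; a rerun with
the same manifest reproduces the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, Thresholds, config_hash
from . import feedscan, fdpstats, io, synthgen, trackmetrics

logger = logging.getLogger(__name__)

MODEL_METRICS = ["travel_km", "max_disp_km", "flight_elev_m",
                 "straightness", "mean_speed", "departure_h", "active"]


class PipelineError(RuntimeError):
    pass


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def summarize_daily(daily: pd.DataFrame) -> dict:
    """Population-level daily-metric summaries (the generator-calibration
    quantities: activity level, straightness, departure time)."""
    ok = daily.loc[~daily["missing_day"].astype(bool)]
    active = ok["active"].astype(bool)
    act = ok.loc[active]
    dep = act.loc[~act["departure_censored"].astype(bool), "departure_h"].dropna()
    n_cens = int(act["departure_censored"].astype(bool).sum())
    return {
        "n_days": int(len(ok)),
        "n_missing_days": int(daily["missing_day"].astype(bool).sum()),
        "prop_active": float(active.mean()) if len(ok) else float("nan"),
        "mean_straightness_active": float(act["straightness"].mean()),
        "mean_departure_h": float(dep.mean()) if len(dep) else float("nan"),
        "prop_departure_censored": (n_cens / len(act)) if len(act) else float("nan"),
        "mean_travel_km_active": float(act["travel_km"].mean()),
        "prop_interpolated": float(ok["n_interpolated"].sum()
                                   / max(1, ok["n_fixes"].sum())),
    }


def analyze(daily: pd.DataFrame, stops: pd.DataFrame, sites: pd.DataFrame,
            thresholds: Thresholds | None = None, subset: str = "all",
            fit_grand_means: bool = False) -> dict:
    """Feeding events, FDP sequences and the full statistical analysis."""
    th = thresholds or Thresholds()
    classified = feedscan.classify_stops(stops, sites, th)
    events = feedscan.build_feeding_events(classified, sites)
    events = feedscan.compute_fdp(events, daily, classified, th)
    events_used = feedscan.subset_events(events, subset)
    sequences = feedscan.build_sequences(events_used, daily, th)
    counts, monthly = feedscan.fdp_histogram(events_used, th)

    report: dict = {
        "subset": subset,
        "n_events": int(len(events)),
        "n_events_used": int(len(events_used)),
        "n_valid_events": int(events_used["valid"].sum()) if len(events_used) else 0,
        "exclusions": (events_used["exclusion_reason"].value_counts().to_dict()
                       if len(events_used) else {}),
        "prop_at_sfs": float(events["at_sfs"].mean()) if len(events) else None,
        "fdp_histogram": [int(c) for c in counts],
        "monthly_long_fdp": monthly.to_dict("records"),
        "daily_summary": summarize_daily(daily),
    }
    if counts.sum() and (counts > 0).sum() >= 3:
        amplitude, rate, r2 = fdpstats.fit_exponential_fdp(
            counts[:th.model_max_fdp + 1])
        report["exponential_fit"] = {"amplitude": amplitude, "rate": rate,
                                     "r_squared": r2}
    zero = counts[0] / counts.sum() if counts.sum() else float("nan")
    report["prop_fdp_zero"] = float(zero)

    models: dict = {}
    if len(sequences):
        for metric in MODEL_METRICS:
            try:
                cells, summary = fdpstats.per_vulture_day_means(
                    sequences, metric, max_fdp=th.model_max_fdp)
                fits = fdpstats.fit_response_models(cells,
                                                    grand_means=fit_grand_means)
            except ValueError as exc:
                models[metric] = {"error": str(exc)}
                continue
            models[metric] = {
                "day_profile": summary.to_dict("records"),
                "fits": [dataclasses.asdict(f) | {"vertex": f.vertex}
                         for f in fits],
                "selected": fdpstats.selected_model(fits).model,
            }
    report["response_models"] = models

    if len(events_used):
        contrast = fdpstats.hungry_vs_satiated(daily, events_used)
        report["hungry_vs_satiated"] = contrast.to_dict("records")

    anova: dict = {}
    if len(sequences):
        for metric in MODEL_METRICS:
            try:
                tab = fdpstats.rm_anova_short_long(sequences, metric,
                                                   thresholds=th)
            except ValueError as exc:
                anova[metric] = {"error": str(exc)}
                continue
            anova[metric] = {"n_subjects": tab.n_subjects,
                             "degenerate": tab.degenerate,
                             "effects": tab.effects.to_dict("records")}
    report["rm_anova"] = anova

    report["_tables"] = {"events": events, "events_used": events_used,
                         "sequences": sequences, "classified_stops": classified}
    return report


def render_markdown(report: dict) -> str:
    """Short human-readable rendering of the analysis report."""
    lines = ["# fdpscan analysis report", ""]
    ds = report["daily_summary"]
    lines += [
        f"- animal-days analysed: {ds['n_days']} "
        f"({ds['n_missing_days']} missing)",
        f"- proportion of active days: {ds['prop_active']:.3f}",
        f"- mean straightness (active days): "
        f"{ds['mean_straightness_active']:.3f}",
        f"- mean roost departure after sunrise: "
        f"{ds['mean_departure_h']:.2f} h "
        f"({ds['prop_departure_censored']:.1%} left-censored)",
        f"- feeding events: {report['n_events']} "
        f"({report['n_valid_events']} with known FDP; subset "
        f"{report['subset']!r})",
        f"- events with FDP = 0: {report['prop_fdp_zero']:.1%}",
    ]
    if "exponential_fit" in report:
        e = report["exponential_fit"]
        lines.append(
            f"- FDP histogram fit: Y = {e['amplitude']:.0f} "
            f"exp(-{e['rate']:.2f} x), R^2 = {e['r_squared']:.3f}")
    lines += ["", "## Response models (AICc)", ""]
    lines.append("| metric | selected | vertex (d) | delta constant | delta linear | delta quadratic |")
    lines.append("|---|---|---|---|---|---|")
    for metric, m in report.get("response_models", {}).items():
        if "error" in m:
            lines.append(f"| {metric} | (not fit: {m['error']}) | | | | |")
            continue
        deltas = {f["model"]: f["delta"] for f in m["fits"]}
        sel = next(f for f in m["fits"] if f["selected"])
        vtx = sel["vertex"]
        vtx_s = f"{vtx:.2f}" if vtx is not None and np.isfinite(vtx) else "-"
        lines.append(
            f"| {metric} | {m['selected']} | {vtx_s} | "
            f"{deltas.get('constant', float('nan')):.2f} | "
            f"{deltas.get('linear', float('nan')):.2f} | "
            f"{deltas.get('quadratic', float('nan')):.2f} |")
    if "hungry_vs_satiated" in report:
        lines += ["", "## Hungry vs satiated (day before vs day after feeding)", ""]
        lines.append("| metric | n | before | after | p | significant (BY) |")
        lines.append("|---|---|---|---|---|---|")
        for r in report["hungry_vs_satiated"]:
            if r.get("p") is None or (isinstance(r.get("p"), float)
                                      and not np.isfinite(r["p"])):
                lines.append(f"| {r['metric']} | {r['n_animals']} | - | - | - | - |")
            else:
                lines.append(
                    f"| {r['metric']} | {r['n_animals']} | "
                    f"{r['mean_before']:.3f} | {r['mean_after']:.3f} | "
                    f"{r['p']:.4f} | {r['significant']} |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            ds = synthgen.simulate_population(sim_cfg)
            synthgen.write_dataset(ds, out / "data")
            fixes, behaviors = ds.fixes, ds.behaviors
            sites, sunrise = ds.sites, ds.sunrise
        else:
            if not all((cfg.fixes_path, cfg.behaviors_path, cfg.sites_path,
                        cfg.sunrise_path)):
                raise PipelineError(
                    "either configure simulate: or provide all input paths")
            fixes = io.read_fix_table(cfg.fixes_path)
            behaviors = io.read_behavior_table(cfg.behaviors_path)
            sites = io.read_site_table(cfg.sites_path)
            sunrise = io.read_sunrise_table(cfg.sunrise_path)

        stage = "metrics"
        daily, stops = trackmetrics.compute_all_metrics(
            fixes, behaviors, sunrise, cfg.thresholds)
        daily.to_csv(out / "daily_metrics.csv", index=False)
        stops.to_csv(out / "stops.csv", index=False)

        stage = "analyze"
        report = analyze(daily, stops, sites, cfg.thresholds, cfg.subset,
                         cfg.fit_grand_means)
        tables = report.pop("_tables")
        tables["events"].to_csv(out / "events.csv", index=False)
        tables["sequences"].to_csv(out / "sequences.csv", index=False)

        stage = "report"
        payload = _jsonable(report)
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))
        (out / "report.md").write_text(render_markdown(report))
        manifest = {
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "subset": cfg.subset,
            "fdpscan_version": __version__,
            "outputs": sorted(p.name for p in out.glob("*.csv"))
            + ["report.json", "report.md"],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete: %s", out)
    report["_tables"] = tables
    report["daily"] = daily
    report["stops"] = stops
    return report
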
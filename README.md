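# fdpscan

Feeding events, food-deprivation periods and movement responses from
GPS/accelerometer biologging tracks of obligate scavengers.

## The problem

Griffon vultures (*Gyps fulvus*) are obligate scavengers that feed in
irregular, widely spaced bouts — in managed landscapes mostly at
supplementary feeding stations (SFS), otherwise at occasional carcasses.
Combined GPS/accelerometer tags make it possible to infer *when an
unobserved bird actually fed*: accelerometer bursts classified into seven
behaviours (active flight, passive flight, standing, lying, preening,
running, eating) are intersected with ground stops detected in the GPS
track, and conservative rules turn "eating" bursts into feeding events.
The number of whole non-feeding days preceding a feeding event — the
**food-deprivation period (FDP)** — is then a proxy for hunger, and the
question becomes: how do daily movement characteristics (travel distance,
maximal displacement, flight elevation, straightness, departure time,
activity) change with days since feeding?  A hump-shaped response —
movement effort rising over roughly the first five hungry days and falling
afterwards — is the signature of a switch from food-intake maximisation to
energy-expenditure minimisation as starvation risk mounts.

`fdpscan` implements this analysis as a tested pipeline, plus a synthetic
biologging generator whose *paper-default* configuration encodes the study
system's published summary statistics (52 % of feeding events on
consecutive days, ~90 % active days, mean daily straightness 0.617, roost
departure ~3 h after sunrise, 71.4 % of feedings at an SFS, winter-maximal
prevalence of long FDPs).  Because the original field data are not
deposited, the generator is the package's test bed: the pipeline must
recover from synthetic tracks the very quantities the configuration
encodes.

## What the pipeline computes

1. **Daily metrics** (`fdpscan.trackmetrics`) — per animal-day, from 10-min
   fixes on a 12-h duty cycle with linear interpolation of missing slots:
   travel distance (sum of segment lengths), maximal displacement from the
   roost, straightness (2·Dmax/L, clipped to 1), mean speed and flight
   elevation over non-static fixes (ground speed > 4 m/s), roost-departure
   offset from sunrise (left-censored when the bird left before the first
   sample), activity (displacement > 2 km), and day-stops (static within a
   400 m radius for > 20 min) with behaviour-label tallies.
2. **Feeding events and FDPs** (`fdpscan.feedscan`) — stops are classified
   *feeding* by (i) ≥ 2 eating bursts, (ii) 1 eating + ≥ 2 running bursts,
   or (iii) a lone eating burst co-located and co-temporal with another
   tagged animal's feeding stop; 1 eating + 1 running is *undecided*; stops
   in major roost sites never feed.  FDP = whole days between consecutive
   feeding dates; events with missing or undecided days in the gap, unknown
   history, or FDP > 14 d are excluded.
3. **Statistics** (`fdpscan.fdpstats`) — per-vulture day-mean tables
   (pseudo-replication control), AICc selection among no-effect / linear /
   hump (quadratic) response models, the hungry-vs-satiated paired contrast
   with Benjamini–Yekutieli FDR control, a balanced two-way
   repeated-measures ANOVA contrasting short (1–4 d) and long (≥ 6 d)
   sequences over days 1–4, and the negative-exponential fit
   Y = A·e^(−bx) to the FDP histogram.

## Worked example

```python
from fdpscan import SimConfig, simulate_population, analyze
from fdpscan.trackmetrics import compute_all_metrics

cfg = SimConfig(n_vultures=5, n_days=120, seed=7)   # paper-default calibration
ds = simulate_population(cfg)
daily, stops = compute_all_metrics(ds.fixes, ds.behaviors, ds.sunrise)
report = analyze(daily, stops, ds.sites)

s = report["daily_summary"]
print(f"animal-days: {s['n_days']}, active: {s['prop_active']:.1%}")
print(f"mean straightness (active days): {s['mean_straightness_active']:.3f}")
print(f"mean departure after sunrise: {s['mean_departure_h']:.2f} h")
print(f"feeding events: {report['n_events']} "
      f"({report['n_valid_events']} with known FDP)")
for metric in ("travel_km", "max_disp_km", "straightness"):
    m = report["response_models"][metric]
    sel = next(f for f in m["fits"] if f["selected"])
    extra = (f", peak at day {sel['vertex']:.1f}"
             if m["selected"] == "quadratic" else "")
    print(f"{metric}: best model = {m['selected']}{extra}")
```

Output:

```
animal-days: 600, active: 90.8%
mean straightness (active days): 0.633
mean departure after sunrise: 3.19 h
feeding events: 176 (168 with known FDP)
travel_km: best model = quadratic, peak at day 5.0
max_disp_km: best model = quadratic, peak at day 5.0
straightness: best model = constant
```

Travel distance and maximal displacement select the hump model peaking
near day 5 of deprivation — the strategy-switch signature — while
straightness is flat, and the daily summaries sit at the calibrated study
values (90 % activity, straightness ≈ 0.62–0.63, departure ≈ 3 h).

The same stages are available from a shell:

```sh
fdpscan simulate --out data/ --seed 1 --n-vultures 5 --n-days 120
fdpscan metrics --fixes data/fixes.csv --behaviors data/behaviors.csv \
                --sunrise data/sunrise.csv --out metrics.csv
fdpscan feed    --stops stops.csv --sites data/sites.csv \
                --metrics metrics.csv --out events.csv --subset all
fdpscan run     --config cfg.yaml      # full pipeline from YAML
```

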
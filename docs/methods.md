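# Methods

This note documents the models, conventions and numerical choices behind
`fdpscan`: what the analysis pipeline computes, what the synthetic
biologging generator emulates (and deliberately does not), and where the
design was genuinely open.

## 1. Measurement model and analysis conventions

**Sampling design.** GPS fixes and accelerometer (ACC) behaviour bursts
arrive on a shared 10-minute grid inside a 12-hour diurnal duty window
(06:30–18:30 local by default; 73 slots per day). Roughly 10 % of slots
are missing and are filled by linear time-interpolation between the
flanking real fixes, never extrapolating beyond the first or last real fix
of the day. A day with fewer than two real fixes is a *missing day* and is
excluded from all metrics. All geometry is planar, in local metres;
geographic input is projected with a local equirectangular approximation
about the dataset centroid, whose length distortion at the ~100 km extent
of the intended study region is below 0.1 % (verified against a haversine
oracle in the tests).

**Thresholds** (all centralised in `config.Thresholds`; values are the
tracking protocol's):

| quantity | value | convention |
|---|---|---|
| non-static fix | ground speed > 4 m/s | strict inequality |
| active day | max displacement > 2 km | strict inequality |
| day-stop | ≤ 400 m radius, > 20 min span | greedy running-centroid scan |
| FDP validity cap | 14 days | longer gaps treated as tag malfunction |
| model-fit cap | sequences ≤ 10 days | longer runs too rare to average |
| short / long sequence | 1–4 d / ≥ 6 d | 5 d is "mid", outside the contrast |

**Straightness.** A raw travel-distance / displacement ratio exceeds 1,
yet the quantity is reported on [0, 1]; for a central-place forager that
returns to its roost each evening the natural efficiency index is
`2·Dmax / L` clipped to 1 (exact for a straight out-and-back). That is
the default; `Thresholds.straightness_convention = "to_farthest"` switches
to `Dmax / (path length up to the farthest fix)` for comparison.

**Departure time.** Hours from sunrise to the first non-static fix. When
the first sample of the day is already non-static the bird left before
sampling began: the value is left-censored and excluded from averages
(the censored share is reported). Sunrise comes from a per-day table; the
generator writes a fixed 05:42 default rather than computing astronomy —
the analysis only uses the offset.

**Stop detection.** A single left-to-right pass: a stop opens at the
first static fix and extends while each next fix lies within 400 m of the
running centroid; it is emitted when its span strictly exceeds 20 min.
The protocol names only the radius and duration, not a clustering
algorithm; the greedy scan is order-deterministic, O(n), and
translation/rotation invariant (tested).

**Feeding rules.** Stops are classified in two passes: pass 1 applies
rule i (≥ 2 eating bursts) and rule ii (1 eating + ≥ 2 running), plus the
undecided composition (1 eating + 1 running); pass 2 resolves lone-eating
stops by rule iii against *pass-1* feeding stops only, which makes the
outcome independent of animal processing order. "Same time and place" in
rule iii is quantified as temporal overlap of the two stops with centroid
separation ≤ 400 m (reusing the stop radius); both are configurable, as
the source protocol does not state tolerances. Stops inside major roost
sites never feed. Feeding is resolved at day granularity: any feeding
stop makes the day a feeding day.

**FDP bookkeeping.** FDP = days between consecutive feeding dates minus
one (feeding days are not counted). The first event per animal has
unknown history and is excluded. A gap containing a missing day or a day
with an undecided stop invalidates the event; undecided stops on a feeding
day itself do not (they never create events either). An FDP sequence runs
from the opening feeding day (index 0) to the day before the terminal
event (index = FDP).

## 2. Statistics

**Pseudo-replication control.** For each movement metric, all values of
day *i* within a sequence are averaged per animal, so each animal
contributes at most one observation per day index. Sequences longer than
10 days are excluded. Response models are fit to the animal × day cell
values (each animal weighted equally); a `grand_means` switch fits the
per-day grand means instead, since which design the original analysis used
is not stated.

**Model set and AICc.** No effect (Y = C), linear (Y = bX + a) and hump
(Y = aX² + bX + c), fit by ordinary least squares. AICc =
n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting the residual variance
(k = 2, 3, 4) — the standard least-squares convention. An ε-floor of
10⁻¹² on RSS guards exact synthetic fits; n ≤ k+1 renders a model
inadmissible; AICc ties below 10⁻⁹ resolve toward fewer parameters.
Cubic and higher orders are out of scope by design. The hump peak is the
quadratic vertex −b/(2a).

**Paired contrast.** Day-before vs day-after each usable feeding event
(both flanking days tracked and themselves non-feeding), averaged per
animal, compared by a paired t-test (a sign-permutation alternative is
provided), with Benjamini–Yekutieli FDR control across the metric family.
The BY step-up procedure is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_by")`; the test
suite cross-checks it against an independent explicit threshold scan.

**Repeated-measures ANOVA.** Subjects are animals with ≥ 3 long
sequences and ≥ 3 sequences of exactly 4 days; cells are subject means on
days 1–4 of each sequence type (using length-4 sequences for the short
cells keeps the design balanced). The classical sums-of-squares
decomposition (subject, type, day, type × day) is reported against a
single pooled residual stratum; components sum to the total on balanced
data (tested at 10⁻⁹ relative tolerance) and a degenerate flag marks a
vanishing residual. The original report prints degrees of freedom
(e.g. F₁,₄ with 20 subjects) that are not mutually consistent with any
standard layout; this implementation reports its own correct df and makes
no attempt to match the printed ones.

**FDP distribution.** The histogram over FDP 0–10 is fit by least squares
of log counts on day, with R² computed on the count scale against
Y = A·e^(−bx).

## 3. The synthetic generator

The generator emulates the *daily summaries* the analysis consumes, not
vulture biomechanics. Its defaults are the study conditions; they were
fixed by calibration to the published summary values and are not adjusted
per run.

**Feeding process.** Day-to-day feeding is memoryless: each day an animal
feeds with probability p. Homogeneous p = `fdp_p0` = 0.52 makes the FDP
distribution geometric on {0, 1, 2, …} with 52 % zeros and exponential
decay — the maximum-entropy law consistent with the reported negative
exponential. Seasonality multiplies p per calendar month
(`seasonal_multipliers`). The multipliers are derived analytically from
the published monthly prevalence L of long FDPs (≥ 6 d): under the
memoryless model L = (1−p)⁶, so p(month) = 1 − L^(1/6), giving p ≈ 0.27
in January–February (L = 0.15) up to p ≈ 0.39 in May–June (L = 0.05),
with a mild secondary autumn rise. Note the published facts are jointly
over-determined: no single memoryless law yields both 52 % zeros overall
and 15 % winter long-FDPs, so the homogeneous sampler carries the
zero-fraction/exponential facts and the seasonal population model carries
the monthly long-FDP profile. Pipeline exclusions (the two-week cap,
undecided- and missing-day gaps) preferentially remove long events, so
the *measured* winter prevalence runs ~1–3 percentage points below the
encoded 15 %.

**Movement.** Each active day is an out-and-back trip from a fixed
per-animal roost. Expected daily travel distance follows the truncated
quadratic hump μ(d) = base + gain·max(0, 1 − ((d − peak)/peak)²) in
day-within-FDP d, with defaults base 50 km, gain 25 km, peak day 5
(so μ is exactly quadratic on d = 0…10 with vertex 5), and lognormal
day-to-day variation (CV 0.20). The far point sits at distance
D = travel/(2τ) with path tortuosity τ = 1.62; the outbound path is an
S-shaped double circular arc whose *sampled polyline* length equals τ·D
exactly and whose farthest vertex is the endpoint, so measured
straightness is 1/τ = 0.617 by construction. The return retraces the
outbound fixes. Flight-fix altitude follows the same hump shape
(base 300 m, gain 150 m); instantaneous speeds equal segment length over
the 10-min interval (≈ `speed_mean` = 10 m/s by choice of fix count).
Dropping 10 % of fixes and re-interpolating replaces arc vertices with
chord points, shortening the measured path by ~1–3 %; measured
straightness therefore averages ≈ 0.63 rather than 0.617 — inside the
calibration tolerance, and documented here rather than compensated, since
compensating would entangle the generator with the pipeline's
interpolator.

**Departure and activity.** Departure offset after sunrise is
Normal(3.0 h, 1.0 h) truncated at 0. The 1.0 h spread keeps the
pipeline-measured mean (after truncation, 10-min grid quantisation and
duty-window censoring) within the 3 h calibration value; it makes
left-censored departures ~1–2 % of active days rather than the ~9 %
reported for the real system — censoring is exercised, just rarer. Days
are active with probability 0.90 independently of the feeding process;
inactive days stay within ~0.5 km of the roost at static speeds. A
feeding day that is drawn inactive still feeds, at a stop placed
1.1–1.6 km from the roost (outside the roost polygon, inside the
activity radius).

**Stops and behaviours.** The feeding stop sits at the far point (the
carcass is the destination), lasting 100–180 min; with probability 0.714
it is snapped to the supplementary feeding station whose distance best
matches the day's displacement draw. Additional loafing stops
(Poisson-distributed, ~0.5/day, 20–60 min) pause the outbound leg at
interior path vertices; with probability 0.02 such a stop is *ambiguous*
(exactly 1 eating + 1 running burst), exercising the undecided rule.
Feeding compositions satisfy rule i (2 + Poisson eating bursts; 98 %) or
rule ii (1 eating + ≥ 2 running; 2 %); rule iii co-feeding is exercised by
the unit tests rather than generated. Diagnostic eating/running bursts
are placed in interior stop slots and are never dropped, so the
truth-ledger round trip (detected feeding days ≡ true feeding days at
zero label noise) holds exactly under fix dropout; the 10 % burst dropout
applies to filler behaviours. Filler labels draw from standing / lying /
preening (+ occasional passive flight); flight slots are active-flight
with probability 0.15, else passive.

**Truth ledger.** Per animal-day: true feeding flag, day-within-FDP,
activity, station flag, censoring flag. It is carried on the dataset
object for recovery tests only; the analysis path never reads it, and the
CSV writers omit it unless explicitly asked.

**What the generator does not emulate.** Thermal soaring and
meteorology, terrain (altitude is a.s.l. with a flat 400 m ground),
social information transfer, carcass persistence and revisits, meal size,
GPS position error, tag duty-cycle variation between individuals, and
whole missing *days* (missing data arise only from per-slot dropout).
Passing recovery tests therefore shows the pipeline is correct and the
calibration coherent — not that real vultures behave like the generator.

## 4. Problem sizes and determinism

Library-level analyses run at the original study scale if asked; the
packaged recovery runs use 20 animals × 200 days for the movement
calibration quantities and 20 animals × 1 calendar year for the seasonal
quantity, with 4397 sampler draws for the FDP-distribution quantities —
sizes chosen so every Monte-Carlo standard error sits well inside its
acceptance band while the whole recovery completes in minutes on one CPU.
All randomness flows from `numpy.random.SeedSequence(seed)` with one
spawned child stream per animal, so outputs are bit-reproducible for a
given configuration and seed regardless of animal iteration order; the
pipeline writes a manifest (config hash, seed, version) and identical
manifests reproduce identical bytes.

## 5. Known limitations

- The straightness and departure measurements carry small positive biases
  from interpolation and grid quantisation (§3); both are documented
  rather than compensated.
- The pooled-residual ANOVA is a simplification of a full
  per-stratum-error repeated-measures layout; with the packaged balanced
  cell design the F-tests are conservative for the subject-varying
  effects.
- Rule iii's spatial/temporal window is declared, not inferred from data.
- The equirectangular projection is inappropriate beyond a few hundred
  kilometres of extent or at polar latitudes.
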
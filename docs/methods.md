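# Methods

## The inference problem

A trap-nested bumble bee foundress queen carries a passive RFID tag and must
walk through a short tunnel under two antenna cards — an inner card near the
nest chamber and an outer card near the exit hole — every time she leaves or
returns.  A flawless reader would produce exactly two reads per passage, and
the board order would give the direction: inner-then-outer is an exit,
outer-then-inner an entrance.  Real readers miss reads (a tag tilted away
from the antenna, a small queen walking low), re-read a stationary bee, and
lose power during battery changes.  The pipeline reconstructs directed
passages, out-of-nest trips and in-nest stays from this degraded stream.

## Filtering rules

The stages run in a fixed order for each (nest, tag) stream:

1. **Re-read collapse.** Successive same-board reads separated by less than
   the pairing window are collapsed onto the first read.  A stationary bee
   re-detected under one card is not a passage; without this rule a re-read
   burst would spawn phantom pairs.
2. **Pairing.** Successive opposite-board reads with strictly less than 10 s
   between them form a pair.  Pairing is greedy left-to-right — "successive"
   means adjacent — and a consumed read cannot pair again.  A brute-force
   reference that enumerates all adjacent matchings and selects the
   earliest-first maximal one is part of the test suite and agrees with the
   streaming scan on thousands of random short streams.
3. **Direction labels.** Inner-then-outer = EXIT, outer-then-inner =
   ENTRANCE.  The event timestamp is the **second** read of the pair (the
   passage is complete when the bee clears the far card).  The alternative
   convention (first read) shifts every duration by at most one transit time
   (~seconds); fixing one convention makes durations reproducible.
4. **Lone-read relabeling.** A lone read immediately preceded and followed
   by two ENTRANCE events implies an undetected exit between them and is
   relabeled EXIT; the mirror rule gives ENTRANCE.  Flanks are the nearest
   in-time neighbours with no gap limit, taken from the original timeline in
   one pass — two adjacent lone reads disqualify each other.
5. **Spurious inner reads.** A remaining lone inner-board read preceded by
   an entrance or by another lone inner read is a queen standing in the nest
   entrance; it is removed and counted.  All other residual reads
   (outer-board, or inner reads in other contexts) are removed as
   *unresolvable* and logged rather than guessed into passages — inventing a
   direction would fabricate trips.
6. **Intervals.** An exit followed by the next entrance is a trip; an
   entrance followed by the next exit is a stay.  Consecutive same-direction
   events are a missed passage: reported as an anomaly, never bridged or
   imputed.  Leading/trailing partial intervals are not emitted.
7. **Removals.** Trips under 30 s (strictly) are removed first (defecation
   trips, entrance-standing), then any trip whose interval overlaps a
   reader power outage.  Stays overlapping outages are likewise excluded
   from stay statistics; the protocol states this rule only for trips, and
   extending it to stays is the symmetric choice.

Every raw read is accounted for exactly once — pair member, relabeled,
collapsed, spurious, or unresolvable — and the pipeline asserts this
conservation on every run.

Thresholds live in `PipelineConfig`: pairing window 10 s, minimum trip 30 s,
foraging maximum 4 h (longer trips are "extended" and summarised
separately), overnight threshold 8 h, stay classes at 3 min and 4 h, stage
windows of 5 foraging days.  Calendar-day quantities (trips/day, the stage
windows) are computed in a configurable local timezone (default
`America/Denver`); all storage and arithmetic is UTC.

## Descriptive statistics

Per-queen summaries use retained foraging trips (< 4 h) only; means carry
the s.e.m. (sample SD over sqrt(n), undefined below n = 2).  Trips/day is
averaged over every calendar day from the first to the last foraging day
inclusive, counting zero-trip days — the recording is continuous, so an
empty day is a real observation.  An active-days-only variant sits behind a
config switch for reconciliation with tables computed the other way.
Percentages in the fate flow are emitted in three renderings (one decimal,
round-half-up integer, truncated integer) because summary figures in the
literature mix the integer conventions.

## Stage models

Queens qualify for the early window (first 5 foraging days) if they had
larvae in the nest when tagged, and for the late window (last 5 foraging
days) if they went on to produce adult workers; only queens with both
windows — at least 10 distinct foraging days — enter the models.

- **Duration**: linear mixed model on the natural log of trip duration
  (the protocol says only "log-transformed"; natural log makes the
  coefficient a log-ratio), stage fixed, queen random intercept; REML via
  statsmodels MixedLM.  When the random-intercept variance collapses to the
  boundary (zero), the model degenerates to OLS and the Wald test is taken
  from there.
- **Frequency**: negative-binomial mixed model on daily trip counts,
  NB2 parameterisation (variance = mu + mu^2/theta), stage fixed, queen
  random intercept.  No pre-installed Python package fits this model, so it
  is implemented in `queentrack.mixed_nb` by maximum marginal likelihood:
  the random intercept is integrated out per queen with 25-node
  Gauss-Hermite quadrature (the one-node limit is the Laplace
  approximation) and the marginal likelihood is maximised with L-BFGS.
  Standard errors come from the numerically differentiated Hessian, so Wald
  p-values are comparable with other marginal-ML implementations; the test
  suite checks agreement with R's glmmTMB to ~1e-2 on coefficients.
- Both models report a Pearson overdispersion statistic (residual
  chi-square over residual degrees of freedom; values above 1.5 flagged).

Both models treat the measured quantity as the *response*; stage is the
only fixed effect.  No offset is used for partial recording days: the first
and last foraging days are defined by observed trips, so the window days
are close to fully observed.

## Concordance

Inferred events are compared with in-person observation logs inside
observation sessions only, observer events filtered to queens.  Matching is
one-to-one greedy by minimal absolute time difference within a tolerance
(default 120 s — a convention, not a measurement; a sensitivity table over
30/60/120/300 s is emitted, and an optimal assignment matcher is available
behind a flag).  A matched pair with disagreeing directions counts as
mislabeled; an observer event matched only by an unresolvable (direction-
unknown) RFID detection counts separately.  The two headline rates are the
percentage of observer events the RFID system missed or mislabeled, and the
percentage of RFID events absent from the observer log.

## The simulator

Ground truth is an alternating renewal process anchored to a diel cycle.
Trip durations are log-normal parameterised by the median (16.1 min) and a
log-SD of 0.784, which puts the mean at 21.9 min; a 1.5% mixture of long
absences (mean 13.1 h, log-SD 0.3) emulates nights spent outside the nest.
Stays come from a three-component log-normal mixture with component means
52.6 s / 27.0 min / 13.2 h (log-SDs 0.6 / 0.8 / 0.35).  Durations are
reported in the literature only as means, medians and s.e.m.; log-normal
matches the right skew of entrance-record data and is fully determined by
those printed targets.

The diel structure: trips launch during a flight window (default
08:00-18:00 local).  When a daytime stay would cross the window end, the
queen roosts instead with a long-component draw; stay *ends* are not
clamped to the next morning, so the long component is realised exactly as
configured and pre-dawn exits occasionally occur.  Component 3's mixture
weight documents the target mixture but the nightly roost is what realises
it; drawing a 13 h stay mid-day would force night-time trips.  Two
consequences are accepted and documented: realised trips/day lands around
11-15 (within the observed per-queen range of 3-17.6) rather than exactly
at the cross-queen mean, because a ~10 h flight day cannot hold 11.8 trips
of 21.9 min plus stays averaging under 27 min — the published daily budget
does not close exactly under a pure alternating renewal, and the duration
and stay-mixture targets (which are the recovery criteria) take priority.

If a worker-emergence day is set, the queen ceases foraging a uniform 0-7
days afterwards (worker emergence switches queens out of foraging within
about a week).  The last five foraging days can carry multiplicative
late-stage effects (defaults in the study roster: 1.5x trip duration, 2x
daytime stays) producing the early-frequent/late-longer pattern.

The sensor model: each passage emits an inner and an outer read separated
by a uniform(0.5 s, 3 s) transit draw — the true tunnel transit
distribution is unknown; this is a stated assumption.  The second read
lands exactly at the truth event time, so perfect sensing reproduces truth
timestamps with zero error.  Each read is dropped independently with its
board's non-detection probability (default 3%; independence is the
simplest model consistent with the described failure modes), stationary
re-reads are injected (5% per read, gap 0.2-3 s), and reads during the
battery-change schedule (one 5-min outage every 3.5 days) are deleted.

`simulate_study` runs a full season over a fixed roster: 18 queens (5
selected a box without laying eggs, 4 colonized then absconded, 2 died, 4
produced workers only, 3 produced gynes), 9 of them RFID-tracked with
recording spans of 5-31 days, daily one-hour observation sessions and an
observer who misses 4.5% of passages.  Exactly six tracked queens qualify
for both stage windows.

### What the simulator does not model

No spatial foraging, floral landscape, weather, or invader-queen behaviour
(multiple tags at one nest are handled mechanically, each tag independent).
No sub-30 s micro-trips (defecation trips), so the micro-trip filter is
exercised by hand-built fixtures rather than at study scale and the
simulated micro-removal count is honestly zero.  No correlated board
failures, no clock drift, no tag loss.  Passing recovery tests therefore
show the *filtering rules* are implemented correctly and are robust to the
modelled error processes — not that real nests contain no unmodelled ones.

## Numerical choices and degenerate inputs

Equal timestamps on opposite boards are ordered INNER before OUTER
(arbitrary but fixed).  Pairing and removal inequalities are strict
exactly where the rule text says "less than".  Duration-model inputs with
zero response variance, single-queen inputs, and all-zero count responses
raise `DegenerateFitError` rather than returning numbers.  Overlapping
power intervals are merged with a warning; overlapping observation
sessions are an error.  Problem sizes in the test suite (3-30 simulated
days, 30-200 seeds per statistical check) were chosen as the smallest runs
whose pass/fail behaviour is stable across reruns.

## Known limitations

- The relabeling rule cannot recover two consecutive missed passages; they
  surface as anomalies and the spanning interval is dropped, which biases
  trip counts down and (rarely) merges trips at low detection rates.
- Unresolvable reads are discarded, not modelled; at very low detection
  probability most passages end up there.
- The late-window placement for queens whose worker-emergence date is
  right-censored inherits that censoring; the simulator draws a known
  emergence day, so this uncertainty is not exercised.
- The NB mixed model uses non-adaptive Gauss-Hermite quadrature; at much
  larger group sizes or random-effect variances than tested, adaptive
  quadrature would be preferable.
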
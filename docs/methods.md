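# Methods

## Scope and model

`stablenet` models a week-long deployment of reader-less active proximity
tags at a boarding stable and the full data path from radio sensing to
network statistics. The package has two halves: a *generative* half
(facility simulator + tag-firmware emulator) that produces raw tag logs
with known ground truth, and an *analysis* half (cleaning pipeline, daily
network aggregation, centrality/mixing summaries, survey comparison) that
is intended to be applied unchanged to real tag downloads in the same CSV
interchange formats.

Time is integer wall-clock seconds from deployment start (midnight of
day 1); days are numbered 1..n and all sensing happens at 1 Hz, so one
second is the resolution of every quantity in the package. Proximity is
binary ("within detection range"), not a distance: radio physics is
deliberately reduced to a per-second miss probability and an optional
spurious-detection channel, because at 24-h aggregation the quantity that
matters is the in-range second count, not the signal path that produced
it.

## The facility simulator

The simulator generates, for every unordered tag pair, the set of seconds
during which the pair is in range. It is schedule-driven, not
behavioural: horses do not move through space, they occupy co-location
states.

* **Default scenario.** 9 horses in two barn aisles (5 + 4), three
  weekday pastures of three horses each, 6 staff with staggered shifts,
  17 static location tags (pastures 1–4, barn door, two aisles, two
  arenas, wash/grooming stalls, two cross-ties, tack and feed rooms, two
  farm entrances) and one bookkeeping tag — 33 tags over a 7-day
  Tuesday-start week. One horse moves to pasture 4 on days 4–5 (the
  weekend move).
* **Turnout (08:30–16:30).** Halters are hung together on the pasture
  fence, so all halter tags of a pasture's horses are mutually in range
  for the whole window and in range of that pasture's static tag. This
  fence-hook clustering is a property of the deployment protocol, not of
  horse behaviour, and is the reason pasture-mate edges saturate.
* **Nights.** Same-aisle horse pairs meet in alternating exponential
  on/off bouts (mean on 600 s, mean off 3600 s). The renewal process is
  the simplest mechanism that produces the variable day-to-day weights
  seen between aisle neighbours; the on/off means are free parameters of
  the scenario.
* **Transits.** Each pasture move puts a horse tag in range of the barn
  door and its aisle tag for a fixed 60 s window (configurable); people
  visit service locations (tack/feed rooms, pastures) as 60 s entry/exit
  transits, reflecting that such contacts are only recorded on entry and
  exit.
* **Evenings.** Each horse draws a Poisson number (mean 1/day) of
  training/grooming bouts (exponential duration, mean 1800 s) at an
  activity location, handled by a randomly chosen staff member when that
  person is on shift.
* **Storage.** Off shift, person tags sit with the bookkeeping tag:
  continuously in range of it and of each other. These are exactly the
  contacts the cleaning pipeline must delete.

Determinism: every stochastic element draws from a stream keyed by
`(seed, purpose, day, tag ids)` (CRC-based stream keys into numpy's
`default_rng`), so a fixed seed reproduces the stream exactly and
different seeds move bout placement without touching the schedule
skeleton.

`truth_networks` bins the stream into per-day edge lists by direct second
counting (weight = seconds/3600, split exactly at midnight). This is the
oracle for recovery tests; note it deliberately differs from the pipeline
output in two documented ways: the firmware merges in-range bouts
separated by less than the washout, and a recorded event's duration is
end-minus-start of *sensed seconds* (a contiguous k-second bout yields
k−1 s of recorded duration).

## The tag emulator

Each tag runs an independent counter clock starting at battery insertion
(`clock_offset_s` = the wall second of insertion; tag-local time = wall −
offset). For each partner, a session opens at the first sensed second,
stays open while detections continue, and closes once detections cease
for ≥ 30 consecutive seconds (washout); the recorded end time is the last
sensed second, so the washout silence is never counted as contact.
Records are BEGIN / ONGOING / END rows carrying both participants' clock
readings; ONGOING rows are emitted every 60 s of an open session (the
cadence is configurable; only the record count depends on it). Both
participants log every event independently — reconciling those duplicates
is the cleaning pipeline's job, not the firmware's.

Imperfections, all per-tag parameters:

* **Battery** (`battery_life_s`): sensing stops when it elapses; an END
  the tag did not live to write leaves an orphan BEGIN in flash. The
  default parameter generator draws lives ~N(6.2 d, 0.3 d) with a 12%
  chance of early depletion (U(2 d, 5 d)), so most but not all tags
  survive a week-long deployment past day 5.
* **Restarts** (`restart_rate_per_day`, default 0.2, gap 5 s): Poisson
  events during which the tag neither senses nor is sensible. A gap
  shorter than the washout is absorbed into the open session; only gaps
  ≥ 30 s split events.
* **Sensing misses** (`p_miss`, default 0.02/s) and **spurious
  detections** (`p_spurious` against an explicit candidate list, default
  off — used to emulate anomalies such as two wall-mounted tags recording
  each other).
* **Memory**: 16 bytes per record, 524,288 records on 8 MB flash. When
  full the tag keeps transmitting but stores nothing further, so exactly
  the first-capacity records survive.
* **One-partner-at-a-time recording** affects only the order in which
  same-second records are written (a seeded shuffle), never the sensed
  seconds themselves — the serialisation delay is sub-second and below
  the model's resolution.

`ideal=True` parameters (zero offsets, no misses/restarts, effectively
infinite battery) are the configuration for recovery tests: under them
the emulator's event set provably equals a brute-force single-pass
washout segmentation of the truth stream, and the whole pipeline
reproduces the truth networks merged under the washout rule to within
1 s per event.

## Cleaning pipeline decisions

* **Bookkeeping vicinity.** "In the vicinity of the bookkeeping tag" is
  operationalised temporally: an event is deleted if it involves the
  bookkeeping tag, or if it lies wholly inside an interval during which
  either participant was itself in contact with the bookkeeping tag
  (optionally expanded by a slack parameter). Restart gaps in the
  bookkeeping tag's own log open holes in those intervals and can let
  storage contacts leak through — the pipeline exposes this mechanism
  but does not try to hide it, since it mirrors what a real deployment
  observes.
* **Window filtering** clips straddling events to the study window and
  recomputes durations (whole-event dropping is available via
  `clip=False`); clipping is idempotent.
* **Reconciliation** matches the two participants' recordings of one
  physical contact by start-time proximity within 300 s (the default
  battery-insertion stagger bound) and keeps, by default, the
  lexicographically first tag's times (`first_tag`); `mean` and `max`
  policies implement the alternative heuristics of averaging the two
  clocks or keeping the longer recording. Unmatched events survive with
  a `one_sided` flag. Reconciliation can only reduce total event hours.

## Network analysis decisions

* **Day binning** credits an event's whole duration to the day of its
  start time (matching firmware-side aggregation by contact start date);
  a `split_credit` flag provides the calendar-exact alternative for
  sensitivity analysis. Under start-date binning, summed daily weights
  equal total event hours exactly (conservation).
* **Eigenvector normalisation.** The principal eigenvector of the
  weighted adjacency is scaled to unit Euclidean norm with non-negative
  entries, keeping every value in [0, 1] without forcing a value of 1
  (max-entry scaling would). Disconnected graphs are handled per
  connected component (each component's sub-vector has unit norm,
  isolated nodes score 0) and flagged; a component whose incident
  weights are all zero falls back to its unweighted skeleton.
* **`<0.00` cells** in printed triangular matrices are recorded contacts
  of negligible duration: the default parse keeps them as zero-weight
  edges (they count toward degree, not strength); a `drop` policy
  removes them. Only the lower (day-1) triangle of the shipped matrix is
  used as a fixture.
* **Mixing ratio.** Homogeneous mixing is quantified as mean
  within-group cell over mean between-group cell of the tag-level heat
  map; ~1 under unstructured mixing (calibrated on random weighted
  graphs: within [0.8, 1.25] for ≥95% of seeds at n = 50), ≫1 or a zero
  between-group mean (flagged) under block structure.
* **Classification universe.** The 2×2 table is computed over unordered
  horse–horse pairs by default; the `nodes=` argument makes the universe
  explicit because published specificities are sensitive to whether
  non-horse tags enter the table, and a whole-barn survey class forces
  specificity 0 on horse-only pairs. The survey network's barn classes
  are per-aisle by default (`barn_granularity="aisle"`), with
  whole-barn available; multi-pasture horses take their majority-week
  pasture, ties broken lexicographically. Undefined metrics (0/0) are
  NaN, never 0.

## What the synthetic data does and does not show

The simulator reproduces the *structure* real deployments exhibit —
schedule-locked co-location blocks, fence-hook saturation of pasture
pairs, sparse cross-group contact, storage-tag artefacts, clock offsets,
battery attrition near day 6 — so passing tests demonstrate that the
pipeline's segmentation, clock handling, deletion rules and aggregation
are correct against a known truth. It does not model weather-dependent
radio range, horse behaviour within a pasture, or human schedule
irregularity, so absolute contact-hour magnitudes and any field-measured
specificity/PPV values are outside what these tests can certify.

## Problem sizes and tolerances

Default verification runs use a 2-day, 33-tag deployment for recovery
and conservation checks and 50 independently seeded 7-day, 9-horse
deployments for the classification properties; the acceptance script
uses the same sizes. Recovery comparisons allow 1 s per event (the
sensed-seconds duration convention); conservation and centrality checks
are exact to floating-point round-off (1e-9 absolute).
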
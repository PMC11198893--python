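# Methods

## Problem setting

One mechanical brush serves a pen of cows. The brush logs a *rotation
event* (start, duration, direction) every time its arm changes direction;
a sensor at the brush logs *identity detections* (timestamp, animal id).
Neither stream alone identifies who brushed for how long: the rotation log
has durations but no identities, the detection log has identities but
records presence, not use (animals drink at the adjacent water trough,
stand by, or walk past). `brushfuse` estimates per-cow daily brush-use
seconds by fusing the two.

All computation is done in float seconds from the *stream epoch* (midnight
of the first record's day); on disk, timestamps are ISO 8601 with
millisecond precision, and a write/read cycle is exact at that grid.

## Bout model

A *bout* is a maximal run of events used continuously by the same cow(s).
Its first event — the *boundary event* — is defined by the rule:

> boundary(i) ⇔ user-set(i) ≠ user-set(i−1), or gap(i) > 10 s

with gap(i) = start(i) − end(i−1), the brush inactivity preceding the
event. Both thresholds are strict: gap = 10.000 s is *not* a boundary,
and the training filter below keeps gap = 1.001 s but drops 1.000 s.
The first event of a stream is always a boundary; its gap is encoded as
`SENTINEL_FIRST` = 86 400 s, which keeps the feature numeric and pushes it
firmly to the boundary side.

Because user identity is unknown at inference, boundaries are predicted
from rotation features alone: (gap, duration, direction∈{−1,+1}), plus by
default (`context_k=1`) the same triple for one neighbour on each side
with validity flags (zero-filled at stream edges). `context_k=0`
reproduces the bare three-feature representation; both are supported
because neighbourhood context helps with short-gap user changes without
changing the label definition.

Training keeps only events with gap > 1 s. Back-to-back events are
almost all continuations, so the filter removes a large, nearly pure
negative mass and rebalances the classes (in default simulations, from
roughly 30:1 to roughly 2:1). Class weighting (`balanced`) is applied on
top. Candidate families: logistic regression, random forest, SVM — each
behind a standardizing pipeline, selected by stratified 5-fold
cross-validated grid search maximizing boundary-class F1. Default grids
are small and explicit: LR C ∈ {0.01, 0.1, 1, 10}; RF trees ∈ {100, 300};
SVM kernel {linear, rbf} × C ∈ {0.1, 1, 10}.

At inference the default **hybrid rule layer** overrides the classifier
where the label is already decided: gap > 10 s is forced boundary (true by
definition) and gap ≤ 1 s forced non-boundary (the classifier never saw
that region). `classifier_only` mode disables both overrides; the first
event is a boundary in either mode. Bouts are assembled by grouping
events between consecutive predicted boundaries; bout duration defaults to
the sum of member event durations (rotation time ≈ contact time), with a
`span` convention (last end − first start) selectable.

## Attribution model

For each unit (event or bout) with span [s, e] and midpoint m, every
animal's nearest detection within ±120 s of m defines a signed interval:
0 if any detection falls inside [s, e] ("during"), otherwise t − m for the
detection minimizing |t − m|. The four animals with smallest |interval|
fill four ordered candidate slots; ties are broken in favour of
detections at or before the unit (the animal was already there), then
lexicographically by id. Units with fewer than four nearby animals get
empty slots imputed with +86 400 s (`SENTINEL_FAR`), and no validity flag
is added — the model input stays the four signed intervals.

The 120 s window is a design choice: the candidate count is capped at
four, but without a horizon an animal detected hours away could be
nominated; 120 s is long relative to any plausible walk-up yet short
relative to inter-visit spacing. It is exposed in configuration.

*Proximity* predicts {slot-1 animal} (empty if no candidate). The
*multilabel model* fits one binary classifier per slot (target: "slot-j's
animal is a true user") by cross-validated grid search on per-slot F1;
slots with single-class training targets fall back to a constant
predictor. Predictions on empty slots are suppressed; an all-negative
unit stays unattributed (no silent proximity fallback, so the two methods
remain cleanly comparable).

The default family for both unit kinds is the **random forest**. At the
bundled simulation's scale, a small MLP on four inputs collapses onto the
"slot 1 is the user" rule and becomes indistinguishable from proximity,
while the forest learns the displacement patterns that arise when a
bystander read steals slot 1 (e.g. intervals (0, 0.3, far, far) with the
true user in slot 2) and measurably beats proximity on the sparse stream.
MLP and gradient boosting remain available and selectable.

## Aggregation and evaluation

Attributed unit durations are summed into an animal × day table.
`credit=full` (default) gives every predicted user the whole unit duration
— ground truth measures each animal's own use, including simultaneous
co-use; `credit=split` divides it equally (conserving total seconds).
Unattributed units contribute nothing and are counted.

Metrics: precision/recall/F1 over boundary flags; Average Jaccard over
predicted vs. true user sets; per-slot precision/recall with macro
averages over slots where the ratio is defined; Pearson r between
estimated and true daily totals over cow-day pairs (24 points for one
test day), with animals missing from either table counted as 0 s.
Undefined ratios are reported as NaN, never zero — silently zeroing
precision on empty predictions would make method comparisons misleading.
One deliberate extension of the Jaccard formula: a unit where both sets
are empty scores 1 (the prediction correctly asserts "no user"; the raw
ratio is 0/0).

The comparison harness trains on the first two simulated days, tests on
the third, and reports Average Jaccard and daily-use Pearson r for the
eight cells {vision, rfid} × {event, bout} × {proximity, ml}, plus the
boundary report for the bout path. Bout-level training uses true bouts;
bout-level testing uses predicted bouts, whose truth sets are the union of
member events' true users — so bout cells inherit segmentation errors, as
they would on real data.

## Synthetic herd

The simulator emulates a 24-cow pen over 3 days with one brush.

* **Visits**: per cow per day Poisson(4); durations lognormal
  (median 60 s, σ = 0.9) truncated to [10, 1800] s. Daily per-cow totals
  then span roughly one to twenty-seven minutes, bracketing the range
  reported from direct observation of such pens (≈59–1610 s). Visits
  never overlap (one brush). With probability 0.2 the next visit (always
  a different cow) starts within 10 s of the previous one ("quick
  succession", producing user-change boundaries that rotation data cannot
  resolve); otherwise inter-visit gaps are 10.5 s plus an
  exponential-flavoured partition of the day's remaining free time, so
  inactivity boundaries sit strictly above the 10 s rule and day packing
  is always feasible (a genuinely over-full day raises an error). With
  probability 0.05 a second cow shares part of a visit (multi-user truth
  sets).
* **Events** tile each visit: durations gamma (mean 5 s, shape 2),
  intra-visit gaps exponential (mean 0.5 s) truncated below 10 s,
  direction flipping with probability 0.8. All times land on the
  millisecond grid.
* **Detections**: during a visit the user is read once per period
  (vision 1 s, RFID 3 s) with independent miss probability (vision 0.1,
  RFID 0.5) and Gaussian jitter (σ = 0.3 s). Bystander reads arrive as a
  Poisson process (default 6/h), naming a uniformly random non-visiting
  animal. Co-users are read during their shared stretch.
* **Ground truth** maps each event to its visit by midpoint containment
  and derives exact user sets, boundary flags, true bouts and daily
  totals.

Everything is deterministic given the seed; schedule, events and each
detection stream draw from independent seeded substreams, so regenerating
one stream never perturbs another.

These distribution families and scales are modelling stand-ins: no public
dataset describes brush-visit micro-structure, so they were chosen as
standard positive right-skewed duration models with scales matched to the
reported daily-use range. The simulator also omits real-world structure —
milking-time absences, diurnal rhythm, social displacement at the brush,
spatial occlusion geometry (subsumed into the miss probability), and the
heavy-tailed detection dropout of barn RFID. Passing tests therefore
demonstrate that the fusion pipeline is correct and well-behaved under
controlled, realistic-scale conditions, not that any particular accuracy
will be achieved in a barn. Notably, the simulated RFID profile (a read
every 3 s at 50% miss) still identifies nearly every visit, so event-level
cells saturate near r ≈ 1 and the vision-vs-RFID margin is carried by the
bout cells; barn RFID is typically far lossier.

## Numerical and testing choices

* Strict inequalities throughout (">10 s", ">1 s"), read literally.
* The noiseless test profile zeroes every stochastic confusion channel:
  misses, jitter, bystanders, co-use *and* quick succession — the last
  because a user change behind a sub-10 s gap is undecidable from rotation
  features alone, so it is a confusion channel rather than a noise level.
  In that profile the full chain recovers truth exactly (boundary F1 = 1,
  Jaccard = 1, daily-use r = 1).
* Monotone degradation with miss rate is asserted on the sparse
  (RFID-grade) stream, where each read carries non-redundant information;
  on the dense stream redundancy masks misses and the effect is within
  seed noise. Monotonicity is tested as non-increasing means plus a
  one-sided sign test (α = 0.05) across 20 seeds.
* The "confuser regime" for the ML-vs-proximity comparison is 120
  bystander reads/hour (20× default, ≈2/min). The ML advantage is largest
  at low-to-moderate confusion and fades at extreme rates, where slot
  ties make the task ambiguous for both methods.
* Multi-seed tests use 20 seeds with 3-fold CV and single-candidate grids
  per seed to keep the suite fast; the acceptance script runs the full
  documented grids once.
* Degenerate inputs: single-class boundary training raises; single-class
  attribution slots warn and use constant predictors; Pearson with < 3
  pairs or zero variance returns NaN; empty Jaccard input raises;
  malformed CSV rows are dropped and reported rather than aborting a run.

## Known limitations

* Boundary recall is structurally limited by quick-succession user
  changes; the hybrid layer guarantees precision on long-gap boundaries
  but cannot create information the rotation stream lacks.
* The multilabel model sees only four signed intervals (by design); it
  cannot disambiguate exact ties, and per-slot F1 optimization is not
  Jaccard-optimal.
* Pearson on 24 cow-days is a coarse, scale-insensitive validation; it is
  reported because it is the field's customary summary, not because it is
  powerful.
* The simulator's noise is stationary and independent across reads; real
  sensors fail in bursts.
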
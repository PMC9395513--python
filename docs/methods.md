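# Methods

`ctmt` re-implements the analysis pipeline of a computerised Trail
Making Test (cTMT): participants connect 20 encircled items in order
(part A: numbers 1–20; part B: alternating 1, A, 2, B, …, 10, J) by
dragging a cursor while gaze is recorded at 1 kHz. This note documents
the models, conventions and defaults each stage uses, what the
synthetic agent does and does not emulate, and the numerical choices
made where the procedure left them open.

## Stimulus generation

Item positions are drawn one at a time on a 30×30 node lattice with
20 px spacing (600×600 px extent; items are 10 px-radius circles at
node centres). The first node is uniform; each subsequent node is
proposed by independent horizontal and vertical displacements whose
magnitudes are Poisson(μ = 5) in grid units with uniform random signs;
a (0, 0) net displacement is resampled. A proposal is rejected when it
leaves the grid, lands on an occupied node, or when the straight stroke
to it crosses any earlier stroke; after bounded retries the whole
layout restarts. A finished 20-item path is accepted only if the convex
hull of its item centres covers more than 40 % of the 600×600 px area
(denominator: the full extent).

Crossing conventions: proper intersections and collinear overlaps count
as crossings; consecutive strokes share an item and their common
endpoint does not. The predicate uses exact integer orientation tests
(grid coordinates are integral), so there is no floating-point
ambiguity during construction.

Under these defaults the accepted-set hull coverage settles at about
(50 ± 7) % — an emergent property of the displacement law plus the 40 %
filter, not a tuned quantity. Which layouts become type A versus type B
is decided at labelling time, mirroring per-participant randomisation
of trial type over a fixed layout set.

## Event detection

Gaze is parsed with a velocity–acceleration scheme using the thresholds
conventionally used for cognitive experiments: 30 °/s velocity,
8000 °/s² acceleration, 0.1 ° minimum motion. Positions are first
smoothed with an 11 ms moving average; velocity and acceleration are
then estimated by central differences over a ±2-sample window. A
saccade is a maximal run of samples exceeding the velocity or
acceleration criterion whose net displacement also exceeds the motion
criterion; runs shorter than 3 samples merge into their neighbours
(anti-flicker); boundary samples belong to the saccade. Complementary
runs are fixations (centroid = mean of member samples); signal gaps
longer than 20 ms become blinks and split the surrounding fixations.

The smoothing is needed because at 1 kHz even 0.1 ° of white positional
noise produces sample-to-sample velocity noise far above 30 °/s;
after the 11 ms average plus 4 ms central difference the noise-induced
velocity sd at 0.1 ° noise is ≈ 8 °/s, and residual threshold flickers
are absorbed by the motion criterion and the anti-flicker merge. With
the synthetic agent the detector recovers the scheduled fixation count
exactly in ≥ 95 % of trials at that noise level.

The pixel↔degree factor defaults to 29.3°/1024 px ≈ 0.0286 °/px from
the stated viewing geometry (19″ screen at 65 cm). A printed conversion
of 0.022 °/px circulates for the same setup and is inconsistent with
that geometry; both are supported, the geometric one is the default,
and results in pixel units are unaffected either way.

Before pooling eye-movement statistics, fixations longer than 1000 ms
and saccades longer than 100 ms are discarded, and pooled samples may
be subsampled by a configurable factor (canonically 10, "an order of
magnitude") with a seeded uniform draw.

## Trial performance

A target is reached when the cursor path comes within 10 px of its
centre. The test is exact per path segment (quadratic roots of the
segment–circle intersection), so a fast jump across a circle between
two logged samples still registers, and a leave-and-re-enter inside one
sampling gap counts as two entries.

A trial is *completed* when the first 12 items are entered in order
within the 25 s limit, where "in order" means an ordered subsequence of
all entries: wrong items touched and then corrected are tolerated,
because participants were instructed to correct their trajectories. RT
is the time from button press to the 12th in-order entry. A trial is
*correct* when it is completed, no out-of-order item is entered before
completion, and the drawn path never touches itself (simplicity of the
cursor polyline; tangency counts as touching). This is the only reading
under which completed and correct can differ, which the downstream
metrics require. Whether "percentage of completion" (PC) itself demands
strict correctness is configurable (`require_correct`); the default is
completion-only.

Per participant and condition, PC is the percentage of completed
trials and RT is summarised by the median (robust; configurable).
The individual-differences normalisation is the B/A ratio: PC-B/PC-A
(Completion Ratio) and RT-B/RT-A (RT Ratio). Learning effects are
assessed by comparing chronological first and last thirds of the
trials; with a remainder the extra trials go to the earlier terciles
(100 → 34/33/33).

## Phase parsing

Fixations are classified by their relation to the cursor. Before the
first hand movement — the first time the cursor moves more than 2 px
from its button-press position (the 2 px guard absorbs sensor jitter;
0 restores the literal reading) — fixations are *exploration*. After
it, a fixation is *monitoring* if the instantaneous gaze position comes
strictly within 25 px of the zero-order-hold cursor at any sampled
moment of the fixation, else *planning*; a minimum distance of exactly
25 px is planning. A fixation straddling the first movement counts as
exploration when its onset precedes the movement (onset rule,
configurable to an offset rule; the choice was genuinely open).

## Working memory: Targets Remembered (TR)

Fixations are attributed to items by nearest centre within 50 px
(~1.4 ° at the default conversion), ties toward the earlier item in
path order. The 50 px radius is a documented default — no attribution
rule is canonical — and TR's sensitivity to it should be checked when
porting to real data.

A concatenated target T (counted from the second target onward; the
first has no previous-target departure to anchor the window) is
*remembered* when (a) at least one fixation attributed to T ends at or
before the hand's departure from the previous target (last timestamp
inside its 10 px circle), and (b) no fixation attributed to T ends
strictly inside the window from that departure to T's entry. Any number
of intervening fixations on *other* items is irrelevant. Only correct
trials enter the metric. Per participant: mean TR per condition and the
TR-B/TR-A ratio; the block-wise variant computes the ratio per block of
20 trials and drops blocks with fewer than 3 correct trials in either
part.

The external working-memory reference is the change-detection capacity
K = N_set·(2·correct/all − 1) per set size (4 or 6), with K_average
their mean.

## Inhibitory control: projection curves and AUC

For every item-attributed fixation the hand path over the fixation
interval (zero-order-hold cursor at 1 ms) is translated so the hand
position at fixation onset is the origin, projected on the unit vector
toward the fixated item, and normalised by the onset-to-item distance:
the item sits at projected coordinate 1 (2-D form: at (1, 0)).
Fixations on the next unreached item in sequence are Correct
Detections; all others are False Detections (fixations on
already-passed items are included — the printed definition draws no
further distinction). Events whose onset hand position coincides with
the item are dropped.

Mean curves are formed per 1 ms lag over the events still ongoing at
that lag (ragged averaging). Fixation durations mostly fall below the
300 ms integration bound, so some pooling convention is forced; ragged
averaging uses all data, and a truncation mode (only events spanning
the window) is available behind a flag. The inhibition index is the
trapezoidal integral of (Correct − False) over 50–300 ms after fixation
onset, computed participant by participant, in dimensionless
displacement × seconds; only within-pipeline comparisons are
meaningful.

## Statistics

* Wilcoxon signed-rank, two-sided, zeros dropped, average ranks for
  ties. For n ≤ 15 the p-value is exact: the tie-aware null
  distribution of W⁺ is built by convolution over doubled ranks
  (integer arithmetic), and p = min(1, 2·min(P≤, P≥)). Beyond 15 the
  tie-corrected normal approximation with continuity correction is
  used; the two agree to < 0.02 in the overlap region. The signed z is
  always reported because the effect size is e.s. = |z|/√n (reported
  positive; n = number of pairs entering the test — with 49
  participants √49 = 7 reproduces the printed effect sizes).
* Kuiper's two-sample test: V = sup(F₁−F₂) + sup(F₂−F₁) over pooled
  points; p from the asymptotic series with effective
  n = n₁n₂/(n₁+n₂), truncated at 100 terms with an underflow guard.
  Chosen over Kolmogorov–Smirnov for even sensitivity across the whole
  support.
* Spearman correlation with average ranks (delegated to scipy).
* Monte-Carlo power: each iteration draws n values from
  Normal(mean, sd) and applies the exact two-sided signed-rank test at
  α. Draws are continuous, so ties and zeros have probability zero and
  the exact null distribution depends only on n — it is computed once,
  making 10 000 iterations take well under a second. The canonical
  design point is n = 12, Normal(−15, 10) (a standardised effect of
  1.5), 10 000 iterations; the stated μ/σ pair is printed ambiguously
  across PC and RT scales in the source material, but both
  parameterisations imply the same standardised effect and therefore
  the same power.
* No multiple-testing correction anywhere, by design.

## The synthetic agent

The agent generates complete sessions — 1 kHz gaze, movement-only
mouse logs, strict A/B alternation in blocks — with ground truth for
every stage. It is a generator of statistically plausible scanpaths,
not a model of human strategy.

Per trial: a configurable number of exploration fixations on randomly
inspected items precede the first hand movement. The agent then works
through the trail. Targets among the last `memory_span` distinct
fixated-but-unreached items are reached directly while gaze inspects
other items — these are the ground-truth remembered targets. Forgotten
targets require search fixations (nearest-unvisited policy with a
randomised inspection order; each search fixation finds the true next
target with probability `search_accuracy`); the final fixation on the
found target lingers so that it ends strictly between the hand's
departure and arrival — the "seen right before selecting" case that
must not count as remembered. On false-detection fixations, with
probability `false_drift_prob` the hand makes an out-and-back excursion
toward the fixated item, covering `false_drift_gain` of the distance
(capped at 150 px and by the fixation's duration at hand speed) after a
30 ms motor-capture latency, returning 2–4 px beside its anchor so the
trail does not retrace itself.

Hand legs are routed to keep the drawn curve simple and clear of
foreign item circles: each new leg is checked against all earlier legs
(2 px margin; touching counts) and against the reach circles of items
that are not its endpoints (13 px clearance), with recursive detours
around offending obstacles (bounded depth; a leg with no clean detour
is accepted as drawn). Routing failures are the main source of
simulated incorrect trials, roughly a third of trials at default
settings — which is desirable: the correct/complete distinction needs
non-degenerate data on both sides.

Saccades use a symmetric triangular-velocity profile scaled so the
peak velocity equals the `saccade_peak_velocity` parameter (duration
2·amplitude/peak); no main-sequence fitting. Gaze noise is white and
positional. Scene fixations (when no unvisited item is available) hop
30–60 px so their saccades stay above the detection thresholds.

Defaults, chosen once as plausible study-scale values: memory span 3;
fixation durations Gamma(shape 4, scale 50 ms), clipped to 80–900 ms;
saccade peak velocity 300 °/s; hand speed 600 px/s; false-drift
probability 0.3, gain 0.35; gaze noise 0.03 ° sd; 3 exploration
fixations; search accuracy 0.6. These yield 12-item completion in
roughly 4–7 s and a few dozen fixations per trial. All randomness
derives from one session seed via `SeedSequence` spawning; identical
seeds give byte-identical streams.

What the agent does **not** emulate: A/B difficulty differences (it
treats both trail types identically, so B/A ratios hover near 1),
fixation drift or microsaccades, blinks, saccadic undershoot, smooth
pursuit of the cursor, speed–accuracy trade-offs, learning or fatigue.
Passing recovery tests therefore demonstrates that the pipeline
measures what the generator encodes (memory span, drift tendency,
event schedule) — not that human data would behave this way.

## Recovery experiments and problem sizes

The test suite runs reduced, seed-fixed experiments chosen to finish in
minutes:

* TR ↔ memory span: 20 simulated participants with spans 0…6, six-trial
  sessions on a shared layout pool; Spearman rank correlation between
  span and pipeline mean TR must exceed 0.8 (observed ≈ 0.90).
* Inhibition AUC ↔ drift gain: five gain levels (0–0.6) × six seeds,
  six-trial sessions, with a span-0, always-drifting, low-accuracy
  agent so that search fixations occur while the hand is parked — the
  regime in which the drift pathway is isolated from ordinary
  co-movement of hand and gaze. Mean AUC must be monotone
  non-increasing in the gain and positive at gain 0.
* Event-detection recovery: at 0.1 ° gaze noise, the detected fixation
  count equals the scheduled count in ≥ 95 % of trials.
* Completion-criterion robustness: per trial, completion at the
  12-item criterion implies completion at 10, which implies it at 8.

## Numerical choices and degenerate inputs

Zero-length strokes, empty point sets, empty samples, constant vectors
and all-zero difference vectors raise `ValueError` rather than guess.
Collinear point sets have hull area 0. An all-invalid gaze recording
yields an empty event sequence with a warning. Readers reject
structural violations (non-monotone time, missing columns) with the
offending row; session-structure violations (broken alternation, wrong
block counts) are reported as warnings, never silently repaired.
Division by a zero denominator in any ratio yields a flagged
None/undefined value, not an exception.

## Known limitations

* The inhibition AUC has no external anchor here (the source analysis
  also found no external correlate); only within-pipeline contrasts
  are interpretable.
* The fixation-to-item radius (50 px) and the phase straddle rule are
  conventions; both are configurable and should be sensitivity-checked
  on real recordings.
* The agent's hand-routing heuristic occasionally fails to keep the
  trail simple, producing incorrect trials at a higher rate than
  careful humans would show; recovery statistics are computed on the
  correct subset, as the metric definitions require.
* Real EyeLink EDF/ASC parsing is limited to a minimal sample dialect;
  binocular selection, calibration and drift correction are out of
  scope.
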
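# Methods

This note documents the models, conventions, parameter choices, and
known limitations behind `placerep`.

## Coordinate frame and geometry

All positions are in cm in the camera image frame: x grows east, y
grows south, so "north" means decreasing y; cardinal directions are
image-relative, not compass-relative. The standard maze is a walled
platform (default 60.96 × 91.44 cm) with six square blocks (default
19.1 cm; the as-built 18.4 cm value is available via
`build_standard_maze(block_size_cm=...)`) in a 2×3 grid, leaving equal
gaps. The gaps tile into 17 alleys and 12 intersections on a 3×4
intersection lattice; columns and rows of that lattice define 3
vertical and 4 horizontal corridors. All rectangles are half-open,
`[x0, x1) × [y0, y1)`, so every point maps to exactly one region. The
pixel conversion defaults to 10 px = 2.1 cm, making the ratemap bin
(10 px) exactly 2.1 cm.

## Synthetic sessions

The generator is the package's testing ground: its defaults describe
the conditions the analysis assumes, and every downstream statistic is
validated against it.

**Trajectory.** A random walk over the region graph: the animal moves
between intersection and alley centers at a per-traversal speed drawn
from N(22, 7) cm/s (clipped at 3), rendered to 30 Hz frames with 0.5 cm
Gaussian positional jitter. At each intersection the next alley is
drawn with three biases: a backtrack damping (weight 0.05 on the alley
just traversed — rats rarely immediately reverse), a reward attraction
(with probability 0.3 the choice is biased toward the alley-graph-
nearest primed site), and a *rotation bias*: the probability that the
next entry continues clockwise circulation around the platform. The
rotation bias is the flow-conserving way to bias direction sampling —
a fixed per-alley direction preference cannot persist in a closed maze
because every crossing must eventually be matched by a return. Each
entry becomes a turnaround (exit through the entry end) with
probability 0.12. Two reward sites are primed at all times; a visited
site is replaced by one at alley-graph distance ≥ 2, and rewards are
stamped when the animal reaches the lickport (alley center).

**Cells.** Each cell has 1–7 isotropic Gaussian fields (multi-fielded
with probability 0.65; field-count weights decline from 2 toward 7,
matching the observation that repeating cells carry two to seven
fields) centered on region centers, scale 2.5–4.5 cm, peak 4–12 Hz,
baseline 0.05 Hz. With alignment strength s (default 0.8) each alley
field lands in the cell's preferred orientation with probability s and
uniformly over alleys otherwise; 10 % of fields sit at intersections.
Half of the alley fields carry a ×2 directional gain on one travel
direction. 40 % of fields drift under one of four envelope families —
constant, linear ramp, exponential decay with onset delay, slow
sinusoid — chosen to mimic the qualitative drift patterns seen in
recordings (monotone decay/growth, antiphase oscillation, delayed
onset).

**Spikes.** The rate at frame t is baseline + Σ fields
peak·G(position)·gain(direction(t))·drift(t), where direction(t) is the
*pass-level* travel direction of the current alley traversal (not
instantaneous heading). Spike counts are Poisson per 33.3 ms frame
(piecewise-constant-rate discretization; error is O(λΔt) and negligible
at place-cell rates), with spike times jittered uniformly within the
frame. Identical seeds give bit-identical sessions.

**Pass-level generator.** For statistics that operate on per-pass
normalized rates, `simulate_pass_table` skips the spatial layer: pass
times uniform over the session, balanced directions, and normalized
rates with mean gain·drift(t). Its default noise model is pure counting
statistics — Poisson(ν·mean)/ν with ν = 5 expected spikes per pass —
because a field with *no* behavioral modulation produces exactly
counting noise; an over-dispersed Gamma alternative (`noise="gamma"`)
models additional pass-to-pass gain variability.

**What the generator does not emulate.** Theta-scale temporal
structure, within-field place-phase coupling, realistic trajectory
stereotypy beyond the three choice biases, anisotropic or wall-hugging
fields, and spike-sorting artifacts. Tests passing on this generator
therefore validate the *analysis chain*, not claims about real tissue.

## Ratemaps and field detection

Position samples below 1.5 cm/s running speed (centered finite
difference of lightly smoothed position) are excluded from both spike
counts and occupancy. Counts and occupancy are binned at 2.1 cm,
smoothed separately with a 1.5-bin Gaussian restricted to walkable
bins, and divided; bins with zero raw occupancy are invalid (NaN), not
zero. Detection then proceeds in order: (1) local maxima at least 4
bins (40 px) apart (Chebyshev distance, square footprint); (2)
8-connected region growing around each peak admitting bins at ≥ 20 % of
that peak (bins already claimed by a higher peak are not re-claimed, so
fields partition); (3) area ≥ 1 % of walkable bins and peak ≥ 1 Hz; (4)
iterative two-marker watershed splitting — a split of a field at a pair
of in-field maxima is accepted only if both parts pass the thresholds
*and* the boundary between them is at most 75 % of the larger peak,
where the boundary rate is the highest rate on bins of one part
8-adjacent to the other (the ridge, equal to the max-min barrier
between the peaks); accepted parts are split recursively, ties broken
by descending peak rate then row-major order; (5) fields whose
95th-percentile bin rate is below 1 Hz are dropped. Units with log₁₀
mean session rate > 0.6 (≈ 4 Hz, putative interneurons) are excluded
beforehand; the boundary case is kept (strict inequality). Manual
curation of field boundaries is replaced by automated QC flags
(oversized fields > 15 % of walkable bins are flagged, never silently
altered).

Region assignment: a field is present in a region when it covers ≥ 30 %
of the region's bins; if several regions qualify, each is kept only if
its bins carry ≥ 25 % of the field's summed rate. Alley memberships are
then regrouped into vertical/horizontal *orientation portions* (the
field's bins inside alleys of that orientation), which are the units of
all directional analyses.

## Traversals and normalized rates

A pass is a run of consecutive in-boundary frames; exits shorter than
2 s merge into the same pass; a pass needs at least two points at depth
≥ 5 % of the shorter of the boundary's y-extent (length) or x-extent
(width) from the nearest border (Euclidean distance). Alley entrances
are the two short ends; the travel direction runs entry end → exit end,
same-end passes are turnarounds and excluded, as are passes containing
a reward event in their alley and time span (a toggle retains them for
robustness re-analysis). A field portion enters analysis only with at
least two clean passes in each direction.

The normalized pass rate divides the unsmoothed single-pass ratemap
bin-wise by the session ratemap and averages over visited bins (bins
with zero session rate excluded), which corrects for passes that clip
different parts of the field.

## Repetition and the OAS

A repeating cell has ≥ 2 fields in one location type (vertical alley,
horizontal alley, intersection); extra fields elsewhere do not
disqualify it. The OAS considers alley fields only: with n fields and
majority count m, the alignment ratio m/n is located in the ascending
list of achievable ratios k/n, k = ⌈n/2⌉…n, and its 1-based rank is
divided by the list length. Ratio arithmetic is exact (`fractions`);
rounding happens only at presentation. The population test permutes the
pooled alley-field orientation labels and re-deals them preserving each
cell's field count, which conserves total and per-cell counts exactly;
the observed mean OAS over multi-fielded cells is compared one-sided to
the null 95th percentile.

## GLMs

The dependent variable is the normalized pass rate + 1 (the offset
keeps the Gamma support); the family is Gamma with an inverse link.
Time enters as a natural cubic spline with 3 degrees of freedom
(patsy `cr`, boundary knots at the first/last pass times); current/
previous/next direction are binary with north/east coded 1. The
direction test compares base = spline(time) against base + direction;
the time test compares base = direction against base + spline(time),
at α = 0.05/6 ≈ 0.0083 (3 spline df × up to 2 orientations per field);
prospective/retrospective tests add previous/next direction over
time + current direction. The LRT statistic is the analysis-of-deviance
form (dev_base − dev_alt)/φ with φ the alternative model's
deviance-based dispersion, referred to chi-square on the parameter
difference. Non-converging fits are flagged and excluded from counts
rather than imputed.

Calibration: under the counting-noise null the direction LRT rejects at
5.0–5.5 % (nominal 5 %) at 40 passes per direction. The chi-square
reference is sensitive to response skewness — strongly skewed
over-dispersed noise (Gamma shape ≈ 4) inflates rejection to ~8 % at
this sample size, the same small-sample effect that makes shuffle-based
fictive rates exceed the nominal level on real data — so shuffle
controls remain the primary guard. The 3-df time test is mildly
conservative (~2–3 %) at these sizes and approaches α as passes
accumulate; it is never anticonservative.

## Field pairs and the dip statistic

All unordered same-orientation field pairs within a cell are tagged
same/different corridor via the host alleys. Paired directionality
indices (DI = directional mean difference over the field mean, positive
= north/east) are related by OLS; the corridor contrast uses a
one-sided Fisher r-to-z test and a label shuffle preserving the two
group sizes (Δr² against the null 95th percentile). Pairs with a zero
DI are excluded from the quadrant sharing counts. Trajectory types are
previous-current-next direction triplets; a pair's trajectory-response
correlation is the Pearson r of mean normalized rates over types
sampled in both fields (≥ 3 shared types required).

The Hartigan dip statistic is implemented exactly: the dip is the
smallest band radius d at which some unimodal CDF (convex, then
concave, an atom allowed at the mode) fits within sup-distance d of the
empirical CDF. Band feasibility reduces to value intervals at the
sorted sample points; whether a convex prefix and a concave suffix can
meet at a mode point is decided with a forward dynamic program over the
achievable (endpoint value, last slope) frontier, and the dip is found
by bisection (60 iterations, ~1e-16 precision). The implementation is
validated in the tests against a brute-force linear-programming oracle
over unimodal CDFs, including tied and atom-at-sample cases; p-values
come from uniform-null Monte Carlo at matched n (default 10,000 draws,
reduced in tests for speed).

## Temporal dynamics

Field rate time series are resampled with monotone PCHIP interpolation
(exact at knots, no overshoot) to the longer of the two lengths before
Pearson correlation; results are invariant to denser resampling.
Population vectors hold each unit's mean normalized rate over alley
passes in each of six equal-duration session windows; the drift summary
is the least-squares slope of between-window correlation against
absolute window lag. Windows with constant vectors are dropped with
NaN rows.

## Decoding

Direction: one population vector per alley pass (per-unit normalized
rates with the session-wide alley activity as denominator), random
forest (1000 trees by default, √features per split), out-of-bag
accuracy as the metric. Significance is conjunctive — the empirical OOB
must exceed the 95th percentile of the label-shuffle null *and* of a
naïve classifier guessing labels in proportion to their empirical
frequencies — so class imbalance alone cannot pass; the conjunction
keeps the false-positive rate at or below 5 %.

Position: per-frame features are spike trains convolved with a Gaussian
(σ = 25 frames, truncated at 4σ, so kernel support of 100 frames stays
inside the 500-frame buffers), standardized; linear regression predicts
x and y separately; r² is pooled over train and over test frames of an
alternating 8000-train/1000-test pattern whose boundaries are
circularly rotated (uniform offsets). The null circularly shifts the
position trace against the features by 10 s to duration − 10 s. A
σ = 8 variant checks robustness to the kernel width. The temporal
variant trains on 10,000-frame windows (1000-frame tests, 1000-frame
buffers) and summarizes decay away from the training window with
Spearman correlations before (positive under drift) and after
(negative) it. Repeating/non-repeating contrasts downsample the larger
group to the smaller one's size, ten draws per rotation, with shared
rotation offsets so identical groups difference to exactly zero.

## Validation problem sizes

The end-to-end validation suite runs at sizes chosen to give stable
Monte-Carlo estimates on a single CPU: detection precision/recall on
one 1-hour, 20-cell session (recall and precision are measured on
fields whose drift-averaged peak is ≥ 3 Hz, matching a truth to a
detection via center containment or peak distance within the truth's
1-Hz radius); GLM power at 150 and type-I at 500 replicates of 40
passes/direction; drift power at 100 replicates; PV slope sign over 20
populations; decoder calibration over 20–25 seeded populations and one
15-minute session. Larger replicate counts sharpen the same estimates
but do not change any conclusion.

## Known limitations

- The chi-square LRT reference inherits small-sample skewness
  sensitivity (see GLMs above); shuffle controls are the backstop.
- The behavioral model is a plausible stand-in, not a fit to tracked
  trajectories; stereotypy in real rats is richer.
- Field boundaries are fully automatic; the QC flags mark suspicious
  fields (oversized, regionless) but nothing is hand-curated, so
  skirt-overlap ridges between crowded fields can surface as weak
  (1–2 Hz) detections that a human would prune.
- The OAS shuffle permutes orientation labels (not full field
  identities); with heavily imbalanced orientation pools the null is
  accordingly narrow.
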
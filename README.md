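# placerep

Analysis of hippocampal CA1 place-field **repetition** on a city-block
maze: a walled platform with six square blocks in a 2×3 grid, whose
interstitial spaces form 17 alleys (9 vertical, 8 horizontal) and 12
intersections. Repeating place cells express several fields at
structurally similar locations (e.g. multiple vertical alleys), which
makes them a natural probe of how *positional* inputs (where a field
fires) and *nonpositional* inputs (how strongly it fires — travel
direction, time) are organized.

The package is aimed at electrophysiologists analyzing position-tracked
spike trains from maze foraging, and at modelers who need a fully
synthetic, ground-truthed version of such sessions. It implements, as a
tested library:

- **Maze geometry** — regions, orientations, corridors (straight
  concatenations of collinear alleys), walkable raster, alley graph.
- **Synthetic sessions** — a random walk on the maze graph with two
  pseudorandom reward sites (replacement ≥ 2 alleys away), place cells
  with 1–7 Gaussian fields, optional orientation alignment, per-field
  directional gain and slow drift envelopes, inhomogeneous-Poisson
  spikes at the 30 Hz camera frame rate.
- **Ratemaps and field detection** — speed filtering (1.5 cm/s),
  10-px (2.1 cm) bins, 1.5-bin Gaussian smoothing; local maxima with a
  40-px minimum separation, border expansion to 20 % of the peak, size
  (≥ 1 % of walkable bins) and peak (≥ 1 Hz) thresholds, iterative
  watershed splitting accepted only when the inter-part boundary is
  ≤ 75 % of the larger peak, a post-watershed 95th-percentile ≥ 1 Hz
  rule, and interneuron exclusion (log₁₀ mean rate > 0.6).
- **Traversals** — pass segmentation (2 s merge, interior-depth rule),
  entry-end→exit-end direction labels, turnaround/reward filtering, and
  location-normalized per-pass firing rates.
- **Repetition** — the orientation alignment score (OAS): the rank of a
  cell's majority-orientation ratio among the ratios achievable for its
  field count, normalized to (0, 1]; population significance from a
  shuffle that permutes pooled orientation labels across cells.
- **Directionality** — per-field Mann-Whitney tests, the signed
  directionality index, and Gamma-GLM likelihood-ratio tests (inverse
  link, +1 offset) for current/previous/next direction over a natural
  time-spline base model, with label-shuffle controls.
- **Field pairs** — corridor-wise OLS of paired directionality indices,
  Fisher r-to-z contrasts, size-preserving label shuffles, sampling
  bias, trajectory-response correlations, and an exact Hartigan dip
  statistic (validated against a linear-programming oracle).
- **Temporal dynamics** — time-spline GLM (α = 0.0083), PCHIP-resampled
  field time-series correlations, and population-vector correlations
  across six session windows with their lag slope.
- **Decoding** — random-forest direction decoding judged against both a
  label-shuffle and a frequency-matched naïve classifier (conjunctive
  rule), and linear position decoding from Gaussian-convolved spike
  trains (σ = 25 frames) with rotating 8000/1000-sample train/test
  windows, 500-sample buffers, and a circular position shuffle.

## Worked example

```python
from placerep import build_standard_maze, simulate_session, run_pipeline, PipelineConfig
from placerep.synthetic import PopulationParams

geom = build_standard_maze()
session, cells = simulate_session(
    geom, duration_s=1200.0,
    population_params=PopulationParams(n_cells=8, p_drifting=0.3), seed=11,
)
results = run_pipeline(session, PipelineConfig(seed=3))
ot = results["oas_test"]
print(len(results["fields"]), "fields detected from",
      sum(len(c.fields) for c in cells), "planted")
print("mean OAS %.3f vs shuffle 95th %.3f" % (ot["mean_oas"], ot["null_95th"]))
print("PV lag slope %.3f" % results["pv"]["slope"])
```

prints

```
22 fields detected from 20 planted
mean OAS 1.000 vs shuffle 95th 0.917
PV lag slope -0.350
```

i.e. the detector recovers the planted field layout (two extra
detections are watershed splits of broad fields); the multi-fielded
cells of this seed happen to be perfectly orientation-aligned, and
their mean OAS of 1.0 exceeds the shuffle's 95th percentile — the
population repeats more than chance placement would produce; and
window-to-window population-vector correlations fall with lag, the
signature of slow representational drift. Shorter single-capability
scripts live in `examples/`.

A thin CLI wraps the same library for shell use:
`placerep simulate | analyze | decode` (see `placerep --help`).

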
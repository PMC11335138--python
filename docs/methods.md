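# Methods

This note documents the models, estimators and numerical conventions behind
`celltracks`, and the choices made where several defensible definitions
exist.

## Data model

A dataset is a pair of tables sharing the key
`unique_track_id = "<file stem>::<source track id>"`, which is
collision-proof across fields of view and human-readable. The spot table
has one row per tracked object per frame (calibrated `x, y[, z]`, integer
`frame ≥ 0`, continuous `t`); the track table has one row per track and
accumulates metric columns. Consistency of the two key sets is checked at
construction. Coordinates stay in the source's calibrated units — tracking
exports are already calibrated, so no pixel conversion is applied unless a
column map explicitly declares pixel units plus a pixel size. When no time
column is mapped, `t = frame × frame_interval`. Untracked spots (no track
id) are dropped with a logged count. The compiled dataset also records every
`(condition, repeat)` directory seen, so an empty repeat folder still
appears (as zero) in balance counts.

On-disk round trip: `spots.csv` / `tracks.csv` / `dataset.json`, floats at
full `repr` precision and re-parsed with round-trip float parsing, so
save → load is an exact identity.

## Track processing

**Smoothing** replaces each coordinate with a centered moving average over
up to `window` spots (window odd). End windows truncate rather than pad —
no positions are invented. Originals are kept in `*_raw` companion columns
and smoothing always re-reads them, so repeated smoothing does not
compound. Consequence worth knowing: truncation contracts the first and
last step of a track, so whole-track mean speed decreases slightly even for
a perfectly straight track; interior steps (and hence the median speed) and
directionality of collinear tracks are untouched. Metrics are computed on
the smoothed coordinates when smoothing was applied.

**Filtering** applies keep-if rules: duration `≥ min_duration` (inclusive:
a track "lasting less than 25 s" is removed), spot count `> min_spots` and
total path length `> min_total_distance` (strict: "more than 6 spots",
"greater than 89 µm"). A spot threshold ≤ 1 or a zero duration/distance
threshold disables that rule, making the all-default filter the identity.
Filtering whole tracks is idempotent by construction.

## Track metrics

For positions `p_0..p_{n−1}` at times `t_0..t_{n−1}` (sorted by frame),
steps `v_i = p_{i+1} − p_i`, lengths `ℓ_i`, step speeds `s_i = ℓ_i / Δt_i`:

| metric | definition |
|---|---|
| Track Duration | `t_{n−1} − t_0` |
| Total Distance Traveled | `Σ ℓ_i` |
| TRACK_DISPLACEMENT | `\|p_{n−1} − p_0\|` |
| Directionality = CONFINEMENT_RATIO | displacement / total distance; 0 when total = 0 |
| Tortuosity | total / displacement; NaN when displacement = 0 |
| Mean/Median/Max/Min Speed, Speed SD | statistics of `s_i` (SD sample, ddof = 1) |
| MEAN_STRAIGHT_LINE_SPEED | displacement / duration |
| LINEARITY_OF_FORWARD_PROGRESSION | straight-line speed / mean speed |
| MAX_DISTANCE_TRAVELED | `max_i \|p_i − p_0\|` |
| Total Turning Angle | `Σ θ_i`, `θ_i = ∠(v_i, v_{i+1}) ∈ [0, π]` |
| MEAN_DIRECTIONAL_CHANGE_RATE | `mean_i(θ_i / Δt_{i+1})` (leading step's duration) |
| Spatial Coverage | convex-hull area of `{p_i}` (0 below 3 non-collinear points) |
| NUMBER_GAPS / LONGEST_GAP | count of frame jumps > 1 / largest jump − 1 |

Conventions: turning angles are unsigned (magnitude reading, valid in 3-D);
a zero-length step contributes θ = 0. The confinement ratio is defined
identical to directionality (net-over-total path length) — the two names
circulate for the same quantity and no distinction is made here. Spatial
coverage uses the convex hull as the simplest parameter-free area measure.
Single-spot tracks get zero duration/distances and NaN speeds. The engine
is column-vectorized over the whole spot table; the test suite holds it to
within 1e-9 of an independent naive per-track loop (stdlib + shapely) on a
thousand random tracks, including degenerate ones.

Spot-feature aggregation produces `S_F` columns (e.g. `MEAN_CIRCULARITY`)
for each numeric spot feature and requested statistic; NaN spot values are
ignored and STD is the sample SD (NaN for a single observation).

## Statistics

**Cohen's d** uses the pooled sample SD,
`d = (mean_a − mean_b) / s_p`,
`s_p² = ((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2)`. Both groups constant
and equal → NaN; zero pooled SD with unequal means is an error (d is
unbounded).

**Randomization test.** The null distribution of |d| is built by relabeling
the pooled values at fixed group sizes. When `C(n_a+n_b, min(n_a,n_b)) ≤
20,000` all assignments are enumerated and the exact fraction at least as
extreme is returned; otherwise `n_iter` seeded assignments are drawn and the
add-one estimate `p = (1 + #extreme) / (1 + n_iter)` is returned, so p is
never 0. Assignments are drawn over the sorted pool with the smaller group
size, which makes the Monte-Carlo p exactly invariant under swapping the
groups. Comparisons against |d_obs| use a 1e-12 slack so ties arising from
floating-point noise count as extreme (conservative).

**Bootstrap SuperPlots t-test.** Per iteration, tracks are resampled with
replacement within each biological repeat; repeat means are averaged into a
group mean; the two bootstrap distributions of group means are compared
with Welch's t-test. This follows the replicate-as-experimental-unit
convention. Caveat (documented deliberately): a t-test between two
bootstrap distributions uses the bootstrap sample count as its degrees of
freedom, so under a data-generating null with *independently drawn* groups
it is anticonservative; its calibration guarantee holds for the exchange of
identical per-repeat data. The randomization test is the calibrated default;
both are reported by the comparison matrix.

**Bonferroni**: `p → min(1, p·m)`, `m` = number of condition pairs.
Boxplot exports follow the Tukey convention (whiskers at the last datum
within 1.5×IQR) and carry ±10×IQR axis-limit metadata.

## Quality control

Balance counts are exact condition × repeat track counts. The similarity
tree summarizes each group (FOV or condition_repeat) by the **median** of
each metric over its tracks (robust to outlier tracks), z-scores features
across groups so large-magnitude metrics cannot dominate, then
agglomerates with distance `1 − cosine similarity` and complete linkage.
Constant columns are dropped before z-scoring; if all columns are constant
the groups are indistinguishable and all distances are 0.

Balanced resampling downsamples every condition × repeat cell to the
smallest cell size, without replacement, seeded; track identity order is
fixed before sampling so results are reproducible. The before/after check
is a per-condition, per-metric two-sample Kolmogorov–Smirnov test; a sound
random resample leaves all p large, a biased one (e.g. top-m by speed) is
flagged.

## Embedding and clustering

The feature matrix z-scores the selected metrics (sample SD); tracks with
any non-finite selected value are dropped with a logged count (tortuosity
is NaN for closed tracks by design), constant columns are dropped.
Embedding defaults mirror common practice for tracking data: UMAP with
`n_neighbors = 10`, `min_dist = 0`, 2 output dimensions, fixed seed
(`random_state` forces single-threaded, bit-reproducible output); t-SNE is
available with perplexity capped at `(n−1)/3`. HDBSCAN
(`sklearn.cluster.HDBSCAN`) runs on either the 2-D embedding or the raw
feature matrix with euclidean or canberra distance — canberra helps when
tracks are kinematically similar, as in collective migration. Defaults
`min_samples = 20`, `min_cluster_size = 200` suit datasets of thousands of
tracks; scale `min_cluster_size` down for small datasets.

Noise (label −1) is kept as its own fingerprint category so each
condition's percentages sum to exactly 100. Cluster profiles z-score each
metric **across cluster means** (not across tracks): the heatmap answers
"how do clusters differ", and a 0/0 (all cluster means equal) is defined as
0. Exemplars are the k tracks nearest their cluster centroid in z-scored
feature space, ties broken by track id.

## Spatial analysis

Ripley's K is estimated as
`K̂(r) = |A| / (n(n−1)) · Σ_{i≠j} 1[d_ij ≤ r]` in a rectangular window,
reported as `L(r) − r = √(K̂/π) − r`. No analytic edge correction is
applied; instead the Monte-Carlo envelope (pointwise α/2 and 1−α/2
quantiles over seeded uniform simulations with the same n and window)
shares the same edge bias, so observation and null are directly
comparable. At small radii relative to the window the residual bias of the
uncorrected estimator is negligible (the CSR-null mean of `L(r) − r` stays
within ±0.01 for r ≤ 0.1 in the unit square — recomputed by the acceptance
script). Each track contributes **one** point, by default its first-frame
position, to avoid temporal pseudo-replication; mean position or a chosen
frame are available.

ROI distances are unsigned Euclidean distances to the boundary: polygons
(closed ring or open polyline, e.g. a leading edge) use exact
point-to-segment distance via shapely; masks use the Euclidean distance
transform of the boundary pixels × pixel size, where the boundary excludes
the image rim (an ROI cut off by the image border has no observable edge
there) — mask and polygon routes agree within one pixel. Per-track
summaries of the distance series `d(t)` include
`DirectionMovement = d(t_{n−1}) − d(t_0)` (positive = ended farther from
the edge), `AvgRateChange = DirectionMovement / duration`,
`PercentageChange` (NaN when the start distance is 0), and `TrendSlope`,
the least-squares slope of d against t. Stratification labels a track
`close` when its maximal edge distance is ≤ 75 µm (ties to close) and
`far` otherwise; the threshold is configurable. Spatial modules reject 3-D
datasets.

## Synthetic data

The generator emulates a Condition/Repeat/FOV experiment with
persistent-biased random walks: step direction is the unit-normalized
mixture `persistence·previous + (1−persistence)·fresh random direction`;
step length is normal truncated at 0 with mean `speed_mean·Δt` and SD
`speed_sd·Δt` (direct mean/SD control; truncation bias is < 2% for the
default mean/SD ratio and vanishes as it grows); an optional constant bias
velocity is added. Tracks reflect at field borders (count-preserving;
flagged in the ground truth) and frames are dropped i.i.d. to create gaps,
with at least two observed frames kept per track. The leading-edge scene
adds a vertical boundary ROI and a designed fraction of tracks that move
straight toward it at an exact speed, making the distance series analytic
(`TrendSlope = −approach_speed` to machine precision).

What the generator does **not** emulate: segmentation noise and jitter in
positions, track fragmentation/identity switches, cell division, spatially
heterogeneous densities, or drift fields. Tests passing on synthetic data
therefore validate the estimators and bookkeeping, not robustness to
upstream tracking errors.

Default study-scale conditions used by the tests and the acceptance
script: effect-size recovery uses 500 tracks/group of 37 frames
(36 steps of per-step SD 3 give a track-mean-speed SD of 0.5, so a
0.5 µm/min shift is exactly 1 pooled SD); clustering recovery uses two
250-point Gaussian blobs 10 SD apart; Ripley uses n = 100 in the unit
square with 100–200 simulations; the oracle suite uses 1,000 random tracks
of up to 40 spots including degenerate 1–2 spot tracks.

## Numerical conventions

Sample SD (ddof = 1) everywhere "SD" appears; seeds are explicit arguments
and logged in run manifests (embedding/cluster defaults: 42); CSVs are
written with full-precision floats and stable column order so byte-equality
is a valid test; Monte-Carlo p-values use add-one smoothing; all
probability outputs lie in (0, 1].

## Known limitations

* No analytic (e.g. isotropic) Ripley edge correction — envelopes carry the
  correction implicitly; absolute `L(r) − r` values near the window scale
  are biased.
* The ROI is static per FOV; a moving leading edge is not tracked over time.
* The bootstrap t-test's anticonservatism under independent-group nulls
  (above); use the randomization test for calibrated error rates.
* No mean-squared-displacement/diffusion fitting, no lineage computation,
  no 3-D spatial statistics.
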
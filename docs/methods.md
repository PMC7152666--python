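# Methods

## Data model

A fixation is (participant, stimulus, x, y, start, duration); coordinates
are screen pixels with origin top-left and y increasing downward, times are
milliseconds. A scanpath is the time-sorted, non-overlapping fixation
sequence of one participant on one stimulus. Saccades are defined only
between consecutive fixations of one scanpath: amplitude is the Euclidean
distance between fixation centers, duration is the gap between one
fixation's end and the next one's start, floored at zero. Overlapping
fixations are a validation error by default (the package assumes an
upstream fixation filter already ran); an opt-in repair mode truncates the
earlier fixation to its successor's start.

## The 16 metrics

Movement measures: `AvgFix` (mean fixation duration, ms), `AvgSac` (mean
saccade amplitude, px), `AvgSacDur` (mean saccade duration, ms), `KCoef`.
Numerosity measures: `FixNum`, `SacNum` (= `FixNum` − 1), `FixRate` and
`SacRate` (counts per second of completion time), `ScanLen` (sum of saccade
amplitudes, px), `CompTime` (ms). Spatial measures of the fixation-position
distribution per axis: `StdX/StdY` (sample standard deviation, n−1
denominator), `SkewX/SkewY` (population-moment skewness g1 = m3/m2^{3/2}),
`KurtX/KurtY` (excess kurtosis g2 = m4/m2² − 3, zero for a normal
distribution — so "higher kurtosis" reads directly as heavier tails).

Choices worth stating:

- **Completion time** defaults to the scanpath's span (first fixation start
  to last fixation end) because stimulus-display timing is not part of the
  fixation data model; an explicit per-trial completion time can be passed
  in and then also drives the rates.
- **K coefficient.** Definition used here: pair every fixation that has an
  outgoing saccade with that saccade's amplitude, z-score durations and
  amplitudes with the *pooled* dataset mean/sd (ddof = 1), and average
  z(d) − z(a) per scanpath. Pooled rather than per-scanpath standardization
  is deliberate: z-scores within one scanpath average to ≈ 0 by
  construction, which would destroy the coefficient's discriminative value
  across participants. Zero pooled variance on either channel yields K = 0
  everywhere with a degeneracy flag. The coefficient is invariant under
  dataset-wide positive affine transforms of durations and of amplitudes.
- **Degenerate scanpaths**: a single fixation has no saccades (`AvgSac` =
  `ScanLen` = 0); skewness/kurtosis need ≥ 3 fixations and a non-constant
  axis, else 0 with a flag.
- **Aggregation across stimuli** is the unweighted mean of per-scanpath
  metric vectors (a per-(participant, stimulus) table is available instead).

## Similarity, weighting, correlations

Metrics are min-max normalized to [0, 1] per column before any distance is
taken, so differently scaled metrics are commensurable under affine
weights; constant columns map to 0 and are flagged. Per metric, the
pairwise similarity value is stored as a *dissimilarity* |m_i − m_l|
(0 = identical) — standard clustering semantics — and is converted to a
perceptual direction only in color encoding. Affine combinations require
weights that sum to 1 within 1e-9 (explicit renormalization flag
otherwise). Metric–metric association uses Pearson correlation across
participants; a constant metric gets correlation 0 with a flag so the
metric dendrogram stays computable.

## Clustering

Agglomerative hierarchical clustering with average linkage (UPGMA) by
default, single/complete selectable. The implementation is a direct O(p³)
agglomeration with Lance–Williams updates and explicit tie-breaking by
smallest cluster index: participant counts here are tens, so determinism
was preferred over asymptotics (the test suite checks it against both a
from-scratch reference agglomeration and scipy). Flat groups come from a
k-cut or height-cut of the merge list; leaf order puts the child containing
the smallest leaf index first. Metric ordering clusters the correlation
matrix under d = 1 − |r| (default), so anti-correlated — equally
redundant — metric pairs also become adjacent; d = 1 − r is available.

## DSSM layout and color

The sub-grid side is the minimal power of two with g² ≥ n (4 × 4 for 16
metrics). Metric rank k in the dendrogram leaf order occupies the k-th cell
of a fixed-orientation Hilbert curve (start top-left, end top-right;
consecutive cells always share an edge), so adjacent ranks are spatially
adjacent. Unused tail cells render neutral gray.

Base colors are CIELAB LCh hues starting at h0 = 0° with a 20° step
(16 × 20° = 320°, leaving a deliberate gap rather than stretching the
step), chroma 50 and reference lightness 60. A similarity value v ∈ [0, 1]
sets lightness L = 30 + 60·v: identical pairs are darkest (configurable
direction). CIELAB→sRGB conversion is done in-package (D65); out-of-gamut
colors are mapped by bisecting chroma toward the neutral axis, which
preserves the hue that identifies the metric. The conversion round-trips
sRGB within one 8-bit unit and matches scikit-image's converter in tests.
`palette_discriminability` reports the minimum pairwise ΔE of the palette
(17.36 for the default 16 colors, computed, not asserted as a constant).

## Parallel coordinates geometry

Axes are unit-height with positions 0..m−1; vertex height is
(v − min)/(max − min), reflected for inverted axes, 0.5 for constant
columns. Brushing selects participants whose vertex lies in a closed
interval; brushes compose by intersection and commute with row deletion
under fixed axis scaling. Smoothing blends the exact polyline with a
shape-preserving piecewise cubic (PCHIP): curve(s) = (1−s)·linear +
s·PCHIP. This interpolates every vertex for any s, is the exact polyline at
s = 0, and cannot overshoot the data range between vertices (a stronger
guarantee than the 0.1·s bound the contract allows). Bundling inserts one
mid-gap control point per axis gap at (1−β)·own_mid + β·group_centroid_mid
and smooths through vertices and controls; axis vertices never move, β = 0
is the identity, β = 1 collapses each group's mid-gap controls onto its
centroid. Per-axis group coloring uses equal-frequency bins by default
(deterministic 1-D k-means selectable). Renders are static matplotlib
SVG/PNG; every figure is reproducible from data plus a JSON run config.

## Synthetic generator

Archetypes control: fixation count (truncated normal, min 2), fixation
durations and saccade amplitudes (lognormal — positive and right-skewed,
as in real gaze recordings), spatial center/spread with a per-axis
skew-normal shape parameter, and a heavy-tail flag (with probability 0.15
the spatial deviation is inflated ×3, raising kurtosis). Positions and
amplitudes are reconciled by a target-pursuit walk: each saccade aims at a
fresh iid draw from the spatial model and travels min(drawn amplitude,
distance to target). With generous amplitudes fixations land on iid spatial
samples, so spatial moments are controlled; with short amplitudes the walk
creeps locally, giving the focal pattern. Timestamps accumulate durations
plus exponential positive gaps, so generated scanpaths always satisfy the
ordering/non-overlap invariants. One global seed fans out to
per-participant substreams, so a prefix of participants is reproducible
independently of the roster size.

The default benchmark plants two well-separated archetypes (focal: 400 ms
fixations, 40 px saccades, compact footprint; ambient: 150 ms, 350 px,
wide footprint), 10 participants × 5 stimuli × ~30 fixations each. These
are the package's standing test conditions, not tuning knobs. What passing
recovery tests shows: the pipeline separates groups whose metric contrast
is large relative to within-group variation. What it does not show:
performance on real gaze data, where group structure is weaker, metrics are
correlated with stimulus content, and fixation filters add noise — the
generator models none of stimulus salience, main-sequence saccade dynamics,
calibration drift or blinks.

## Problem sizes and determinism

Tests and the acceptance script use 20-participant benchmarks with 20
replicate seeds, 200 random matrices up to p = 12 for the clustering
oracle, and Hilbert orders 1–3; these sizes already exercise every code
path and keep a full run in the tens of seconds. All stochastic steps take
an explicit seed; clustering ties break by index, so byte-identical inputs
give byte-identical outputs.

## Known limitations

- Dissimilarities, not affinities, are clustered; interpreting the matrix
  as "similarity" requires the color-encoding inversion.
- Min-max normalization is sensitive to single outlier participants (one
  extreme value compresses everyone else's range).
- No optimal leaf ordering/seriation beyond dendrogram order; no automatic
  choice of the group count k.
- The per-axis 1-D grouping for line coloring is a display device, not a
  statistical clustering.
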
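# Methods

This note documents the models, conventions and numerical choices behind
`cellmot`, in the order data flows through the pipeline.

## Synthetic scenes

The generator emulates videomicroscopy of sparse adherent monolayer
cultures imaged at one frame per ~5 minutes over hours. Cells are rendered
as hard-edged (non-anti-aliased) bright disks (default gray 200) on a dark
background (40) with additive Gaussian noise (sd 5), 8-bit grayscale. Hard
edges make detector behaviour analytic: the distance transform of a clean
disk of radius r peaks at its centre with value ≈ r.

**Motion** is a persistent random walk. Per frame each cell turns by a
wrapped-normal deviate `N(0, 1/κ)` wrapped to (−π, π], where
κ = `turn_concentration` is a single knob spanning the isotropic limit
(κ = 0 draws uniformly on (−π, π], giving E|Δθ| = π/2) to the ballistic
limit (κ = ∞, no turning). Step length is `N(speed_mean, speed_sd)`
truncated at 0. Defaults (speed 3.5 px/frame, κ = 0.6) emulate an
untreated culture whose measured mean speed and angular velocity sit near
3.5 px/frame and 1.35 rad/frame; treated-like behaviour is obtained by
lowering speed and κ.

**Interactions.** Optional pairwise attraction adds a drift of magnitude
`clump_attraction` px/frame toward the centroid of neighbours within six
contact radii — long enough range to nucleate clumps of ≥ 5 cells in a
moderately dense scene. Optional `contact_slowdown` multiplies the step
length of cells currently in contact (0.5 halves it), which is what makes
the in-contact speed feature discriminative in tests. Cells whose centre
crosses the field boundary are removed (ground truth marks them exited);
divisions (rate per cell per frame, default 0) place the daughter one
radius away at a uniform random angle.

`initial_heading` optionally starts all cells at a fixed heading; with
heading 0 and κ = ∞ the trajectory is exactly axis-aligned in floating
point, which is what makes the "angular velocity exactly 0" ballistic
check achievable (an oblique straight line accumulates ~1e−16 heading
noise through coordinate rounding).

What the generator does **not** model: cell shape and deformation, DIC
optics and shading, uneven illumination, focus drift, true adhesion
kinematics, lineage identity. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical assumptions,
not performance on any particular microscope's output. Intensity polarity
is standardized bright-cells/dark-background; invert frames on ingest if
your optics give the opposite.

## Detection and tracking

Per frame: Gaussian blur (default σ = 2 px; σ = 0 skips), fixed-threshold
binarisation (default 120, the midpoint of the synthetic foreground/
background; the threshold is deliberately a user-set constant), then an
exact Euclidean distance transform (background exactly 0). Detection takes
the 8-neighbour local maxima with value ≥ `min_peak_value` (default 3 px,
rejecting noise-scale blobs), accepts them from highest to lowest, and
discards any candidate within `suppression_radius` (default: one expected
cell radius) of an accepted one. Ties in value are broken row-major
(smaller y, then smaller x) so detection is deterministic and independent
of traversal order.

Tracking maximises `dist(p)·exp(−‖p−prev‖²/2σ²)` over a square window of
half-width `search_halfwidth` (default 16 px = 2 radii) clipped at the
field boundary, with `gaussian_sigma` defaulting to one radius; a weighted
maximum below `lost_threshold` (default 1.0 distance units) marks the
track lost. Lost tracks are closed, never re-linked — downstream features
average over whatever tracks exist, so fragmentation biases no statistic.
After each frame, tracks within `duplicate_radius` (one radius) of each
other are pruned, keeping the longer-lived (lower id on tie). Detection
re-runs every `redetect_interval` frames (default 10); detections farther
than `duplicate_radius` from every active track seed new tracks.
Coordinates are 0-based pixel centres, x = column, y = row, origin
top-left; localization is pixel-level by design (no sub-pixel fitting).

## Contacts and clumps

Point tracks carry no shape, so contact is centre distance ≤
`contact_radius` (default two expected radii — touching disks). A clump is
a connected component of the per-frame contact graph with ≥ 5 cells
including the focal cell; `count_self=False` switches to the stricter
"five *other* cells" reading. Clump membership runs are episodes; the
post-contact window is the ≤ 3 frames after an episode's exit, truncated
at track end or clump re-entry so no frame is simultaneously in-contact
and post-contact.

## Features

Per-video features pool *steps* across all tracks rather than averaging
per-track means (`per_track_mean=True` gives the other convention); with
pooling, a track twice as long contributes twice the evidence, which
matches reporting one value per video. A speed step (t → t+1) enters the
in-contact/post-contact statistic iff its start frame t is in the mask
(half-open convention); a turning value, computed at the vertex frame t+1
between two steps, enters iff that vertex frame is in the mask — the turn
happens *at* the vertex, so the vertex's contact state is the natural
attribution. Zero-displacement steps have undefined heading and are
excluded from angular statistics (treating them as heading 0 would bias
persistence). Features over an empty set (no clumps, no post-contact
frames, no steps) are NaN in all outputs and CSVs (empty cells); they are
imputed to 0 only at the classifier input, keeping CGP arithmetic total
while preserving the distinction on disk.

## CGP classifier

Genome: one row of 70 nodes, `levels_back` = 70 (full feed-forward
connectivity — standard for single-row CGP), 10 inputs (the ten features),
one output gene. Each node stores a function gene and two source genes;
unary functions read only the first source, constants none — the extra
genes stay in the genome and can matter after later mutations. Protected
semantics: x/0 → 1, SQRT(x) → √|x|, logical operators read an operand as
true iff > 0 and emit 1.0/0.0, and every node's output is clamped to
±1e100. The clamp makes `evaluate` total (finite output for any valid
genome and finite inputs — deep ×/CUBE chains would otherwise overflow to
inf and then NaN); exported expressions are re-evaluated through helpers
with identical clamping, so expression and genome agree to machine
precision.

Training: features min–max normalised to [0, 1] by training-set ranges
(constant features map to 0); a row is classified positive iff the output
exceeds the decision threshold (default 0). Fitness is training accuracy.
Evolution is (1 + λ) with λ = population − 1 = 9 mutated clones per
generation and 1% per-gene point mutation (resampling uniformly over the
gene's valid range, so a "mutation" can redraw the same value); the parent
is replaced whenever the best offspring is at least as fit — preferring
offspring on ties enables neutral drift through the silent genes, which
materially improves CGP search. Search stops at perfect accuracy or after
10,000 generations. The best-fitness trace is non-decreasing by
construction (elitism).

For train/test experiments the pipeline holds out a stratified fraction
(default 25%) of videos per class, seeded from the global seed.

## ANOVA

Group comparison uses the classical one-way fixed-effects F test
(between-group MS over within-group MS, df (k−1, N−k)), computed via
`scipy.stats.f_oneway` and validated in tests against an explicit
sums-of-squares implementation. Degenerate inputs (zero within-group
variance) raise rather than returning an infinite F. No multiple-testing
correction is applied across the ten per-feature tests; the report says
so.

## Determinism and problem sizes

Every stochastic stage takes a seed; the pipeline derives per-video and
evolution seeds from the global seed via `numpy.random.SeedSequence`
spawning, and CSV/JSON writers use fixed float formats, so a rerun is
byte-identical. Validation runs use desk-scale problems chosen to give
tight statistics at interactive runtimes: tracker recovery on a 400×400
field, 20 cells of radius 8 px, 100 frames (≈ 2,000 scored positions);
kinematic limits on ≥ 10⁴ steps; classifier checks on 12–16 videos per
class over 5 seeds. These sizes are the package's own defaults for its
self-checks and are all configurable.

## Known limitations

- Pixel-level localization; dense contact clusters can merge into one
  distance-transform peak, so in-contact positions are noisier than
  isolated ones.
- No track re-linking or lineage: a division produces a new anonymous
  track, and the cell-count feature measures net tracked population, not
  proliferation per se.
- The contact criterion ignores cell shape; with strongly non-circular
  cells the centre-distance radius under- or over-counts contacts.
- Binary classification only; multi-class problems need one-vs-rest runs.
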
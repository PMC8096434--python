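# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic scenes the package is validated on, and the design
choices made where the design was genuinely open.

## Synthetic scenes

The generator emulates a fixed overhead camera filming N elongated animals
on a static background.

**Motion.** Each agent performs a correlated random walk: per-frame speed is
a normal draw clipped at zero (`speed_mean` 2.5 px/frame, `speed_sd` 0.8),
heading increments are normal (`turn_sd` 0.18 rad/frame), and paths reflect
at the arena border.  Crossings are scheduled as a Poisson process
(`overlap_rate`, expected events per agent per minute); each event steers a
random pair toward the midpoint of their positions extrapolated to the
event frame, so the two paths cross transversally at natural speed rather
than converging head-on and stalling.

**Appearance.** Bodies are tapered capsules (teardrops; length 24 px, width
8 px by default) darker than the background (level 200), each carrying a
fixed per-identity 1-D texture: a sum of four random low-frequency cosines
along the body axis, normalized to unit peak and scaled by
`texture_contrast` (default 40 gray levels — the actual peak modulation).
Additive Gaussian sensor noise (`noise_sd` 3) and 8-bit quantisation
follow.  With `texture_contrast = 0` all agents are identical and identity
learning must fail — the pipeline reports this instead of guessing.

**Geometry of the benchmark scene.** The end-to-end benchmark uses 8 agents
and 1500 frames at 25 Hz in a 1024x1024 arena.  The arena size is chosen to
preserve the body-length-to-frame-width ratio of typical laboratory tank
recordings (bodies span roughly 1/40 of the frame); the identity-accuracy
rule counts a frame as wrong beyond 1% of the video width, which at this
geometry corresponds to ~0.4 body lengths — the same meaning the rule has
at full recording resolution.  At much denser geometries the rule degrades
into a test of centroid pixel noise during every contact.

**What the generator does not emulate.** Lighting drift, shadows, lens
distortion, body deformation (bending), 3-D pitch/roll, reflections at tank
walls, and appearance change over time.  Passing tests on these scenes
demonstrates the algorithmic machinery (association, splitting, posture,
uniqueness-guided training) under controlled conditions; it does not certify
performance on any particular real recording.

## Segmentation

Background per pixel over a uniform frame sample: min, max, mode (8-bit
histogram, ties toward the larger value) or mean.  Foreground is
`|frame − background| ≥ threshold` (default 25 gray levels; an optional
dark-only flag restricts the sign), connected components use 8-connectivity
so thin diagonal extremities stay attached, and components outside
`blob_size_range` are discarded.  Luminance equalization, when enabled,
rescales the frame so its global mean matches the background's.  An
external binary mask video can replace thresholding entirely.

## Tracking

**Prediction.** Position is extrapolated with an exponentially weighted
mean of the last ≤5 velocities (half-life 2 frames), rotated by the mean
angular speed over the horizon — a deliberately light-weight filter; with a
single observation the prediction is the last position.  Measured on the
benchmark scenes the mean prediction error is ~2.7 px at 2.5 px/frame
speeds, which is the practical floor set by the unknowable turn and speed
innovations.

**Match probability.** `p = exp(−d²/(2σ²)) · 0.5^(gap/τ)` with a hard zero
beyond `R = track_max_speed·Δt`, `σ = R/3`, gap the time lost beyond one
frame interval and `τ = max_reassign_time` (0.5 s).  `track_max_speed` is
the one parameter a user must set per video: it should be a generous upper
bound on real speeds (the benchmark uses 500 px/s for ~60 px/s agents).
Setting it too tight makes σ so small that ordinary prediction error fires
the uncertainty rule and fragments trajectories.

**Matching.** Edges above `matching_probability_threshold` (0.1) form a
graph whose connected components are matched independently: depth-first
branch-and-bound over trajectories (sorted by best edge), pruning with the
optimistic suffix bound, exact up to `clique_node_cap` explored nodes
(10^5), then Hungarian fallback on the padded matrix.  The greedy matcher
(blobs in scan order take their best free trajectory) is exposed for very
large groups and is provably ≤ the optimum.  Ties break toward lower
identity, then scan order, making runs bit-reproducible.

**Segments.** A new segment opens when an individual was lost ≥1 frame,
when assignment uncertainty `1 − p` exceeds 0.5, or when the inter-frame
timestamp exceeds 1.5x the running median interval.  Lost individuals stay
matchable for `max_reassign_time`, then leave the active set; in
known-count mode new identities are only created while fewer are active
than the known count.

**Overlap splitting.** When a clique offers fewer blobs than trajectories,
the largest blob is re-thresholded at increasing levels until at least the
expected number of similarly sized components appears (each ≥60% of the
median component size); pixels lost to the higher threshold are re-attached
to the nearest component, so the pieces partition the original blob.  Two
guards matter in practice: a blob is only split if it is at least
`0.6·expected·median individual size` pixels (otherwise a competing ghost
trajectory would shred a single body into fragments), and a blob that
cannot be split is excluded from matching for that frame — assigning a
merged blob to one of its members would hijack that identity, so all
involved individuals stay lost until they are found separately.

## Posture

Outline tracing walks pixel corners clockwise (in image coordinates, y
down), so a single pixel is a valid 4-corner outline and the polygon's
shoelace area equals the pixel count exactly; holes are filled and the
largest component is used for disconnected masks.  Elliptic Fourier
smoothing truncates the complex DFT of the vertex sequence to `n_efd`
descriptors, counting the constant locus term as the first — two
descriptors reconstruct an exact ellipse (the classic single-harmonic
limit); corner-traced outlines have unit-length edges, so the uniform
vertex parameter coincides with arc length.  A triangular-weight circular
moving average is the cheaper alternative.

Head/tail: per-vertex pointiness over a ±5%-of-perimeter window combines
chord shortness `1 − |AB|/(2w)` (total turning, robust when the window
folds around a strongly curved tip) with a small angle term; the global
maximum is the pointiest end (`pointiest_is`, default tail), the opposite
endpoint sits at maximal arc distance, and near-uniform scores flag the
shape as endpoint-ambiguous (round shapes; visual fields are then
unavailable).  The midline walks two cursors from the head along opposite
outline directions in steps of equal arc length ±25%, each step pair
minimizing the left-right chord; midpoints and chord lengths give the
midline and thickness, resampled to `midline_resolution` (25) points.

Normalized crops map the head to a fixed anchor (25% from the left edge,
vertical centre) and the head-to-tail chord to +x with bilinear sampling,
zero outside the mask.  The chord equals the initial midline direction for
a straight body and is markedly more stable against midline jitter than a
local tangent.  Without a midline, alignment falls back to the image-moment
axis (`½·atan2(2µ11, µ20−µ02)`, range [0, 180)), which leaves the
180-degree flip unresolved.

Known pixel-scale limits: the corner-traced polygon of a circle deviates up
to ~4% from the analytic circle, so harmonic counts that resonate with the
staircase track it rather than the ideal shape, and the blunt-end head
vertex moves ~1 px between rotations, bounding midline-length rotation
invariance at ~2% for 100 px bodies.

## Visual fields

Two eyes sit `eye_offset_ratio` (0.1) along the midline from the head,
offset by `eye_separation_ratio` (0.9) of the local half-thickness, gazing
along the local direction ±`eye_rotation`.  Rays at `rays` (512) equal
angular bins (body-relative, bin centres in (−180°, 180°]) intersect every
outline polygon including the focal one; per bin the nearest hit fills
order 1 and later hits from other occluders fill higher orders, each with
identity, distance and body-part (arc position from the occluder's head in
percent of its perimeter) channels.  Each eye's `fov` (260°) window wraps
asymmetrically around its gaze — from straight back on its own side around
to `fov − 180°` past the front on the far side — which tiles the full
circle with a frontal binocular overlap of exactly `2·fov − 360°` (160°),
as in laterally eyed fish.  Because the eyes sit just inside the body,
self-intersections closer than max(2 px, 0.75x the maximal body thickness)
are discarded; only genuine self-occlusion (the body blocking backward
rays) registers.

## Visual identification

**Classifier backends.** Two numpy backends implement the common contract
(fit with a 4:1 validation split, probability predictions summing to 1,
snapshot/restore, determinism per seed): a linear softmax on 16x16
down-sampled crops and an MLP with one 100-unit tanh hidden layer.  Inputs
are scaled by `/127.5 − 1` and centred by the per-feature mean of the first
training set (frozen across later units — centring removes the dominant
constant background component; without it Adam needs an order of magnitude
more epochs).  Training uses Adam on the categorical focal loss (γ=2) with
a per-image ±1 px x-shift augmentation applied at crop resolution (no flips
or rotations — orientation normalization replaces them), stopping on: the
epoch cap (`max_epochs` 150), a plateau (best validation accuracy
unimproved by 10⁻³ for 10 epochs, checked after a 40-epoch warm-up),
overfitting (validation loss rising while training loss falls), or perfect
training accuracy.

**Crop hygiene.** Crops are produced only for frames with a valid posture;
head/tail flips are corrected by the motion direction when the individual
moves faster than 25 px/s (the animals travel head-first); and crops whose
blob area deviates more than 30% from the individual's median area are
rejected — these are merged blobs or split fragments, and they are exactly
the images that poison both training and per-segment averages.

**Training procedure.** Global segments are ranked into video quarters by
middle frame, keeping the best `keep_per_bin` (4) per quarter by (minimum
cells visited, average samples); coverage counts centre-point transitions
on a grid of square cells (10 across the width), which rewards arena sweeps
over tight circling of equal path length.  The initial unit trains on the
best candidate (classes balanced to the smallest class +20%, candidates
with any class under 5 images skipped); chance-level validation accuracy
marks the appearance unlearnable and the run fails explicitly.  Each
accumulation step re-scores the untried candidates — average uniqueness in
5% steps ascending (valleys first), distance to trained regions rounded to
a power of two descending, then coverage and sample count — disqualifies
candidates below half the best uniqueness after five steps, and sweeps the
order until one passes the plausibility check (its predicted identities
must be pairwise unique); implausible candidates are re-queued.  The merged
training set caps each prior segment's contribution in proportion to its
share of global-segment frames under the memory budget (1 GB), with
accepted segments keeping the class labels they were accepted under.  A
retrained model is kept only if mean uniqueness stays within 99% of the
best; training stops when every individual's coverage gap is below 25% of
the video or mean uniqueness exceeds `1 − 0.5/N`.  A final unit retrains on
the fully merged set for at most `max{3, 0.25·max_epochs}` epochs and is
kept only on improvement.

**Assignment.** Per-segment averaged predictions claim identities; a
running-window median (25 frames) first splits segments whose predicted
identity flips persistently.  For an identity contested by overlapping
segments, the ratio of the two maximal probabilities (inverted into (0,1])
defers the decision to the kinematic tracker when it exceeds 0.6, otherwise
`S(p, x)` picks the winner.  Two robustness guards: a rival must overlap by
at least 5 frames (1-3 shared frames are crossing-handover bookkeeping, not
simultaneity) and must carry at least as many images as a trainable class
requires — a one-image segment's averaged probability is noise, and without
the guard such fragments veto 400-frame correct segments.  Unassigned
segments keep their tracker identity; when both assigned neighbours of the
same tracker individual agree, the segment between them inherits their
identity (the tracker asserts continuity; a single-sided neighbour is not
used because swaps happen exactly inside unassignable stretches).

## The preprocessed-video container

Little-endian layout: header (magic `PVS1`, u16 version, u32 width/height,
u8 channels, u64 frame count, raw background image, u64 index offset),
frame chunks (u8 flags, u64 timestamp in µs, u16 blob count; each blob a
u16 bbox and horizontal grayscale runs), and a trailing u64 offset index
for O(1) frame seeks.  Flag bit 0 marks lossless deflate per frame.
Timestamps must be strictly increasing; timestamps may also be ingested
from a sidecar NPZ keyed by frame index.  The layout is original to this
package; compatibility with any external container is not attempted.

## Numerical conventions

Image coordinates: origin top-left, x right, y down, 0-based; pixel (x, y)
occupies [x, x+1)x[y, y+1), so blob centroids carry a +0.5 offset and
outline vertices sit on integer corners.  Angles wrap to (−π, π].  All
randomness flows from explicit seeds (one per scene, one per classifier);
repeated runs are bit-identical.  Problem sizes in the test suite — 1500
frames at 1024 px for the end-to-end benchmark, 200 masks / 200 overlap
events / 500 cliques / 1000 prediction sets for the property benchmarks —
were chosen so the whole suite completes in a few minutes on one core while
keeping every stochastic estimate's sampling error well inside its
assertion margin.

## Known limitations

Strictly 2-D: occlusion is resolved by layering, not geometry, and the
visual field assumes every individual occludes fully.  The kinematic
matcher swaps identities at close passes roughly at chance — that is the
problem the visual-identification stage exists to solve, and the benchmark
reflects it (tracker-only ~85-90%, corrected ~99.7-100%).  Identities
inside merged blobs are unrecoverable until separation; their frames keep
tracker identities and carry degraded centroids.  The classifier backends
are deliberately small; appearance that needs spatial detail beyond a
16x16 crop (fine patterning, subtle shape differences) will defeat them
long before it would defeat a convolutional model.
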
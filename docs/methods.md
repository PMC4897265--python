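# Methods

## Pose representation

A frame is a binary silhouette mask; any nonzero pixel is foreground.
The outer boundary of the largest 8-connected foreground component is
traced with Moore-neighbour border following, starting at the
topmost-then-leftmost foreground pixel, giving an ordered pixel contour
P = {p_1..p_n} (order is normalised to one fixed traversal direction;
the binning itself is order-independent).  Masks with several components
are reduced to the largest with a logged warning, since segmentation
noise typically produces specks around one actor.

From the contour the descriptor is computed centroid-relatively:

* centroid C = (x_c, y_c): arithmetic mean of the contour points;
* distances d_i = ||p_i - C||;
* angle of each point about C, measured in image coordinates (y grows
  downward) as alpha = arccos((y_i - y_c)/d_i) in degrees when
  x_i - x_c >= 0 and 360 - arccos(...) otherwise, so alpha sweeps
  (0, 360] continuously around the centroid; alpha = 0 is mapped to 360.
  The arccos argument is clamped to [-1, 1] against rounding;
* bin s_i = ceil(S * alpha_i / 360) in {1..S}; an angle exactly on a bin
  boundary belongs to the lower-index bin.  A contour point coinciding
  with the centroid (d_i = 0, angle undefined — geometrically
  near-impossible for a boundary point) goes deterministically to bin 1
  with distance 0 rather than raising;
* per-bin summary: `variance` is the *sum* of squared deviations from
  the bin mean (kept as a raw sum; the normalisation below absorbs the
  scale), `max` the largest distance, `range` max - min.  An empty bin
  summarises to 0, the natural "no mass" value that keeps the vector
  length at S;
* unit-sum normalisation, which delivers scale invariance.  When the
  pre-normalisation total is below 1e-9 (e.g. a near-perfect circle
  under `range`) the all-zero vector is returned with a `degenerate`
  flag instead of dividing by zero; downstream Euclidean distances stay
  well defined.

Internally the geometry is evaluated in coordinates relative to the
contour minimum, which makes the descriptor bitwise invariant under
integer translations (the centroid's floating-point division would
otherwise round differently at different absolute offsets).  Rotating a
contour about its centroid by k * (360/S) degrees cyclically shifts the
descriptor by k bins.

**Parameters.** `S` (bins; dimensionality): default 12 — enough angular
resolution to separate articulated shapes while keeping the model small;
useful range roughly 8-46.  `summary`: default `range`, which tracks
local contour spread and is the strongest overall performer of the three
in practice; `max` encodes absolute extent per sector; `variance` only
local dispersion.

## Bag of key poses

Training frames are grouped by (view, action class) and each group is
clustered with K-means (Euclidean distance, seeded k-means++
initialisation, 10 restarts, best inertia kept).  Cluster centres become
key poses labelled with their group; with M views and R classes the bag
holds K x M x R entries.  Groups with fewer than K frames clamp K to the
frame count (logged) instead of failing.  K-means is nondeterministic
across seeds, so the clustering seed is part of the configuration and
evaluation repetitions vary it explicitly.

Each training frame is then matched to its nearest key pose (ties to the
lowest index, for determinism).  Per key pose, `assignments` counts its
matches and `matches` those from its own class; the discriminative
weight is w = matches / assignments, and never-selected key poses keep
w = 0 but stay in the bag — they can still serve as nearest neighbours
at test time, and no removal rule is warranted.  The matching population
is all training frames of every view.

`average_distance` is the mean frame-to-nearest-key-pose distance
recorded while converting the training set — the quantities actually
computed during training.  A plausible alternative reading, the mean
pairwise distance among key poses themselves, is available through
`average_distance_mode="pairwise"`; the assignment-based definition is
the default because it measures the same kind of distance the DTW cost
later compares against.

Finally every training sequence is rewritten as its nearest key poses,
which both captures the temporal evolution and filters frame-level
noise.  The model (config, key-pose features, labels, weights, counters,
average distance, index sequences) serialises to a single versioned JSON
file; floats are emitted via `repr` and round-trip exactly.

## Recognition

Pairwise key-pose cost: with e the Euclidean feature distance and
dev = e - average_distance,

    d(i, j) = e + z * |dev| * w_i * w_j,   z in {-1, +1}.

z follows the weight pairing (thresholds: *ambiguous* w < 0.1,
*discriminative* w > 0.9): both discriminative — sign of dev; both
ambiguous — -1; discriminative with ambiguous — +1; anything else — sign
of dev.  dev = 0 counts as below average (continuity with the dev < 0
branch).  The relevance magnitude uses |dev| so that z alone controls
the direction of the adjustment; combining the signed dev with the z
table would *increase* the cost of well-matching discriminative pairs,
the opposite of the rule's stated purpose of rewarding them.  The
literal signed variant remains available (`signed_relevance=True`) for
comparison, and `use_relevance=False` reduces the cost to plain
Euclidean.  Pair costs, and hence accumulated DTW distances, may be
negative; comparisons stay meaningful because every match uses the same
scheme.

DTW uses the classical recursion
dtw(i,j) = min(dtw(i-1,j), dtw(i,j-1), dtw(i-1,j-1)) + d(kp_i, kp_j')
with dtw(0,0) = 0 and infinite first row/column — no windowing, slope
constraint or path-length normalisation.  Costs are looked up in a
precomputed bag-level pair-cost matrix, so each alignment is a pure
dynamic program over index sequences.

A multiview test sequence is classified per view against *all* stored
training sequences (no hard view filtering — the view-specific key poses
make same-view matches naturally closer, and the camera setup need not
match training); the globally lowest distance fixes both the predicted
class and the best view.  Ties break to the lowest training-sequence
index and the first view in sorted order.  Raw unit-sum features feed
the Euclidean term, and DTW totals are compared unnormalised.

## Synthetic data

The generator emulates the input regime of multiview silhouette
benchmarks: R classes x A actors x Q sequences, each with M synchronized
view streams of binary masks.  Classes are disjoint parametric shape
families — star-shaped polygons r(theta) = r0 (1 + amp cos(m theta +
rot)), one lobe count m and body aspect ratio per class — whose lobe
amplitude and orientation oscillate smoothly with the action phase; each
sequence gets a random phase offset and speed, mimicking timing
variation between performances.  Star-shapedness guarantees one
connected component.  Views apply a fixed affine deformation
(foreshortening-style x-scaling plus an in-plane rotation).  Actor
identity multiplies the shape parameters (amplitude terms, articulation
swing, x-anisotropy) by factors drawn once per actor from
U(1 - j, 1 + j) with j = `actor_scale_jitter`; a *pure* global rescaling
would be invisible to the scale-invariant descriptor, so the jitter
deliberately deforms shape.  Boundary noise flips pixels independently
with probability p on the one-pixel band around the contour (inner and
outer ring), then keeps the largest component so every emitted mask
still yields a usable contour.  The dataset is a pure function of
(config, seed); all randomness flows through per-(actor / sequence /
view) substreams of one seeded generator.

The lobe-amplitude floor is kept high enough (amp in [0.16, 0.28] before
actor jitter) that the class signature never washes out at any phase:
with zero noise and zero jitter the per-(class, view) descriptor clouds
are disjoint, so the end-to-end 100%-accuracy checks probe the pipeline,
not dataset luck.

What the generator does **not** emulate: real limb articulation and
self-occlusion, silhouette holes and incompleteness, camera projection
of a genuinely 3-D body, inter-class shape overlap, and temporal
segmentation errors.  Perfect synthetic accuracy therefore demonstrates
correctness of the machinery, not expected performance on real footage.

## Evaluation protocols

LOSO holds out one multiview sequence per fold (a sequence is the
combination of its views); LOAO holds out all sequences of one actor.
Accuracy is sequence-level — one decision per multiview sequence — and
the confusion matrix rows are true classes.  Reports are canonical JSON
(sorted keys), byte-identical across identical runs.  The (S, K) sweep
runs each cell `repetitions` times with clustering seeds master + 0, 1,
2, ... and scores the cell by the median accuracy (lower median for even
counts, for determinism); among tied maxima the lexicographically lowest
(S, K) wins, preferring cheaper models.

## Problem sizes

The default study conditions are 3 classes x 2 views x 3 actors x 2
sequences x 20 frames on 64 x 64 px masks (18 multiview sequences, 720
frames per view set) with S = 12, K = 3, `range` summary — small enough
that a full LOSO run (18 retrain-and-classify folds) takes a couple of
seconds, yet exercising every multiview code path.  Robustness checks
use boundary noise 0.2 and actor jitter {0, 0.1, 0.3} with medians over
5 seeds.

## Known limitations

* Cross-view invariance is out of scope: a view unseen at training has
  no matching key poses and recognition quality is undefined.
* K-means clustering depends on the order of training frames within a
  group as well as the seed; reports fix both, but reordering training
  data can change a trained model (not its evaluation protocol).
* The relevance adjustment can make DTW distances negative; they are
  rankings, not metrics.
* Weight thresholds 0.1/0.9 are empirical constants, exposed in
  `MatchParams` but not swept by the harness.
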
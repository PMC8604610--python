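# Methods

## The detection model

The apparatus images paw–glass contacts by frustrated internal reflection:
green light injected into the glass escapes only at contact points, so a
footfall is a compact set of pixels whose G channel is far above the dark,
red-lit background.  Detection is therefore a three-stage rule, applied to
the analysis band (the rows between the enclosure walls) of each frame:

1. **Thresholding.**  Keep pixels with `G ≥ green_threshold`.  The
   comparison is inclusive, and deliberately so: the published optimum for
   this class of apparatus (205 of 255) should itself be a keepable value,
   not a boundary exclusion.  The G channel is used as decoded; no
   colour-space conversion, since the signal is engineered into that
   channel by the lighting.
2. **Proximity clustering.**  Single-linkage transitive closure over the
   graph joining pixel pairs within a Euclidean `proximity_threshold`
   (inclusive, default 2 px).  Single-linkage is the right semantics here
   because its purpose is to chain the digit prints — disjoint from the
   palm print — into one footfall.  Two implementations back the same
   contract: a connected-component sweep over a precomputed integer offset
   stencil (used for thresholds ≤ 3 on integer pixel grids, the common
   case) and a KD-tree pair query with union-find for arbitrary thresholds.
   Both are tested for exact partition equality against an independent
   O(n²) brute-force closure.
3. **Size filtering.**  Keep clusters with
   `min_cluster_size ≤ N ≤ max_cluster_size` (inclusive, defaults 65 and
   510 px).  This removes specks and dust below, and tail/nose streaks
   above, the plausible footfall range.

Coordinates are 0-based with x = column (along the trackway) and y = row
(across it), origin top-left.  Cluster centroids are plain coordinate
means; no sub-pixel blob refinement and no watershed splitting of merged
paws (a merged pair is simply one oversized cluster and is usually removed
by the size filter).

## Preprocessing

Barrel distortion from the wide-angle camera is removed with a
single-coefficient radial model: an output pixel at normalised radius ρ
(half-diagonal normalisation, so ρ ∈ [0, 1]) samples the source at
ρ(1 + k₁ρ²), bilinear interpolation, black fill.  One coefficient is
adequate for an action-camera lens and keeps calibration to a single
number; full camera-intrinsics models and automatic checkerboard
calibration are out of scope.  The exact inverse warp (Newton-inverted
radius) is provided for calibration previews and round-trip testing:
warping a straight line and correcting it restores straightness to within
1 px.  Rotation (bilinear, black fill) levels the trackway; cropping to
[crop_y_top, crop_y_bottom) keeps the glass band.  The interactive
parameter-picking GUI of the original apparatus is replaced by a config
file plus a `calibrate` preview command; exact pixel equality with that
system is not a goal, since its distortion model was never specified.
Identity parameters (k₁ = 0, 0°, full-frame crop) are bit-exact no-ops.

## Classification

Frames holding exactly four clusters anchor the labelling: with
left-to-right locomotion the two larger-x clusters are the front paws and,
within each front/rear pair, the smaller-y cluster is the right paw.  A
config flag flips both rules for right-to-left runs; direction reversals
mid-run are not detected (a turning mouse is a documented failure mode of
this classification rule, surfacing as falses in the H:M:F score).
Coordinate ties — measure-zero on real data — break by the other
coordinate, then cluster size descending, so the labelling is a pure
function of geometry and independent of cluster ordering.

Labels then propagate to fixpoint: each pass assigns to every unlabelled
cluster the label of the nearest labelled cluster within `frame_window`
frames and `propagation_distance` pixels, skipping labels already present
in the target's frame.  Conflicts resolve nearest-first (ties: earlier
source frame, then centroid order); the loser waits for a later pass and,
if nothing claims it, ends `Unclassified`.  Labels are never overwritten,
so the iteration is monotone and terminates in at most one pass per
cluster.  `Unclassified` clusters are retained in the output for
diagnostics but excluded from gait extraction.

Window sizing matters and is the one genuinely free design choice here.
Defaults are one frame and 20 px, which suffice whenever every stance
contains a four-cluster anchor frame — true for trots with duty cycle
above 0.5, where the diagonal pairs overlap every half-cycle.  For gaits
with duty cycle ≤ 0.5 there are no mid-run four-paw frames and a label
must cross a full swing gap, so the window must exceed the longest
detection gap (the swing duration, in frames) and the distance threshold
must exceed one stride while staying below the smallest inter-paw spacing.
The recovery analyses in the test suite and acceptance script set
`frame_window = swing + 2` and `propagation_distance = stride + 4` against
a geometry with 40 px left/right and 80 px front/rear separation — the
inequality `stride + 4 < 40` holds by construction.  On real videos these
two values are the ones worth tuning per apparatus.

## Gait parameters

Steps are maximal runs of contact frames per paw, bridging gaps of at most
`gap_tolerance` frames (default 2) so an isolated missed detection does not
split a stance.  The mean frame is `floor((t_f + t_l)/2)` snapped to the
nearest member frame (ties earlier); the step's position is that frame's
centroid.

Durations use step endpoints: stance `R_j = (t_l − t_f)/fps`, swing
`D_j = (t_f^{j+1} − t_l^j)/fps`, both nonnegative by construction.
Averages of consecutive-pair quantities (stride, swing) divide by the
number of values present (S − 1), not S — dividing by S would bias them
low by construction.  The duty cycle `ΣR/(ΣR + ΣD)` is 1 by convention
when no swing was observed.  Cadence is reported per paw (that paw's S
over the run duration) and pooled (all steps over the run duration), since
either reading of "steps per run" is defensible.  Supports use at-least-k
semantics (three-point counts frames with ≥ 3 paws down), which yields the
structural guarantee four-point ≤ three-point; diagonal dual support
counts frames where either diagonal pair is down together.  Supports are
reported both in seconds (shared frames / fps) and as fractions of the run
duration; because the run duration is a frame-interval difference while
contact covers whole frames, a support fraction can marginally exceed 1 on
a run in contact throughout.  Lengths are pixels by default; an optional
`px_per_mm` adds millimetre strides (the apparatus calibration is not
assumed).  Base of support is not computed (no defining formula is
available for this apparatus); swing speed appears only as a per-step
convenience column (stride/swing).

### Quantisation of recovered parameters

With endpoint-based durations, a stance of n true contact frames measures
(n − 1)/fps and hands the missing frame to the adjacent swing.  So on
noise-free data: durations recover to exactly one frame (1/fps); stride to
under 1 px (exact when blobs translate by whole pixels); the duty cycle to
(number of contact phases)/(active frames) — one frame per phase over the
paw's active duration, ≈ 0.036 for a 3-stride, 30-frame-cycle run; and
cadence to S/(fps·RD²) per frame of run-duration error (zero on clean
runs).  These are the tolerances the tests assert; they are properties of
frame quantisation, not of the implementation.

## Evaluation

H:M:F matching is a reconstruction — the original validation
cross-referenced detections with annotations manually and never stated a
spatial rule.  Here a prediction matches a ground-truth box when its
centroid lies inside the box or within `max_match_dist` (default 20 px,
one ROC cell) of the box centre; pairs are accepted greedily by distance,
one-to-one.  Correct-label matches are hits; unmatched boxes are misses;
unmatched predictions and matched-but-mislabelled predictions are falses
(misclassification counts as false, and the mislabelled match consumes the
box rather than double-counting a miss).  Percentages divide by
hits + misses + falses, so H + M + F = 100 exactly before rounding.
Clusters that end `Unclassified` still count as predictions: they are
detections, and scoring them is what makes an injected paw-sized distractor
appear as exactly one false.

The ROC analysis sweeps one detection threshold with the others fixed,
re-running detection from scratch at each grid value.  Events are counted
in 20 × 20-pixel cell units and TN fills the rest of the region's cell
budget, `floor(width · height / 400)` cells per image (301 for a 1720 × 70
band).  Counting all four outcomes in the same cell unit is a deliberate
normalisation choice: mixing per-pixel negatives with per-box positives
would make TPR and FPR incommensurate.  TPR = TP/(TP+FN), FPR = FP/(FP+TN);
undefined rates (no positives at a grid point) are flagged as NaN and
skipped by downstream consumers.  The empirical curve joins consecutive
thresholds with straight lines; AUC is the trapezoidal area after sorting
by FPR and anchoring (0, 0) and (1, 1).  The optimal threshold maximises
Youden's J = TPR − FPR (ties: smaller FPR, then smaller threshold) — the
standard formalisation of "maximum TPR and minimum FPR".  A generic
score-sweep helper (`roc_from_scores`) exists for control experiments,
e.g. verifying that uniform-random scores give AUC ≈ 0.5 through the same
AUC code path.

## The synthetic generator

`mousegait.simulate` emulates what the optics deliver, not what a mouse
looks like: a red-tinted background (RGB ≈ (60, 40, 30)) with ±10 G-channel
shimmer, and footfalls as a palm disk (radius 5) plus four digit disks
(radius 1) just ahead of it — disjoint from the palm but within the 2 px
clustering distance, ≈ 101 px total, inside the 65–510 size window.  Paw
pixels draw G uniformly from [paw_G − 10, paw_G] (default paw_G = 240,
comfortably above the 205 threshold), so intensity statistics are
non-degenerate but bounded.

The gait is a trot: diagonal pairs in phase, pairs half a cycle apart,
paws fixed in world coordinates during stance, each landing one stride
(24 px default) ahead.  Every run opens with a lead-in stand on all four
paws; the offset pair's lead-in stance extends by the half-cycle before
its first lift.  This serves two purposes: it guarantees the four-cluster
anchor frames classification needs under any duty cycle (mice do stand
before running), and it makes every swing gap exactly `swing_frames` long,
which keeps the propagation-window analysis above exact.  Distractors
reproduce the documented failure modes: Poisson-placed bright specks
(≤ 13 px, below the size filter), a 4 × 140 px tail streak (560 px, above
it), and paw-sized nose touches ahead of the animal, placed away from all
paw tracks.  Ground-truth boxes cover footfalls only — distractors are
unannotated, exactly as a human annotator would treat them.

The expected gait summary is computed from the contact schedule alone
(closed form, no rendering), so end-to-end tests compare pipeline output
against values that are exact by construction.  Default problem sizes —
480 × 120 canvas with a 70-row band, 3 strides, ≈ 120 frames per run —
were chosen so a run renders and analyses in well under a second while
every geometric margin (blob size vs. size window, track separation vs.
propagation distance, streak size vs. filter) holds with room to spare;
the full-scale 1920 × 1080 geometry is reachable through the same config.

What passing these tests does *not* show: robustness to real-video
phenomena the generator omits — illumination gradients and vignetting,
partially lifted paws shrinking below the size threshold, motion blur,
paw–paw merging, turning mice, direction reversals, and genuinely ambiguous
annotations.  On real data the H:M:F score is expected to degrade from the
synthetic 100:0:0 toward the low-90s hit rates typical of this class of
apparatus; the synthetic closure results validate the algorithmic chain,
not the optics.

## Numerical conventions and edge cases

- All threshold comparisons inclusive; all frame indices 0-based.
- Detection output is sorted by centroid x descending (stable), so the
  leading paws come first.
- Empty inputs: an empty pixel set clusters to an empty list; a frame
  with no clusters is simply absent from classification; a run with no
  labelled footfall raises rather than emitting a hollow summary.
- A paw with no steps contributes no per-paw entry; the rest of the
  summary is still produced.
- RD = 0 (single-frame run) makes cadence undefined (NaN), not infinite.
- The pipeline consumes no randomness anywhere; only the generator holds
  an RNG, seeded explicitly.  Reruns are byte-identical.
- `.mat` export of the original system is replaced by CSV/JSON.

## Known limitations

- Merged footfalls (two paws touching) are not split.
- Turning or reversing mice are misclassified by design of the
  left-to-right rule; only a whole-run direction flag exists.
- The H:M:F spatial matching rule is this package's reconstruction; other
  reasonable rules (IoU-based, for instance) would score borderline cases
  differently.
- The propagation window/distance must be chosen per apparatus geometry;
  the defaults assume gaits with duty cycle above 0.5.
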
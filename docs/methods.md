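# Methods

## Problem setting

A camera moves at constant velocity along a straight nadir pass over a
field.  Plants are stationary in the world, so in image coordinates
every plant translates by the same per-frame offset until it leaves the
frame.  A detector emits per-frame bounding boxes with confidences.
The pipeline must (i) link boxes across frames into identity-stable
tracks, (ii) report each plant's image position as its box centroid,
and (iii) count each physical plant exactly once.

## Coordinate and file conventions

Pixel coordinates, origin top-left, y downward.  Boxes are stored as
inclusive real-valued corners (x1, y1)–(x2, y2) with x1 < x2, y1 < y2;
MOT width/height rows are converted as x2 = x1 + w, y2 = y1 + h.
Frames are 1-based, following the MOT-challenge convention (the
convention choice is observable only in file I/O).  Detection rows with
a missing or −1 confidence are read as confidence 1.0, matching the MOT
ground-truth dialect.  NMS ties on equal confidence keep the earlier
row, making filtering deterministic.

## Tracker

State per track: (cx, cy, a, h, and velocities), where a = w/h.
Constant-velocity transition with dt = 1 frame.  Process and
measurement noise standard deviations scale with box height (1/20 of h
for positions, 1/160 for velocities; initiation doubles the position
std and uses 10× the velocity std), so uncertainty tracks apparent
object size.  These are the standard weights for this tracker family;
they are not tuned here.  During coasting the predicted aspect and
height are floored at 1e-3 and 1 px: a track missed for several frames
can otherwise extrapolate its size through zero, which has no physical
reading.

Association runs in up to two rounds.  In `appearance_cascade` mode,
confirmed tracks are processed in tiers of ascending
`time_since_update`; within a tier the Hungarian algorithm minimizes
λ·(cosine distance to the track's feature gallery minimum) +
(1−λ)·(Mahalanobis distance / gate), with pairs discarded when the
squared Mahalanobis distance exceeds the chi-square 95% quantile at
4 d.o.f. (≈ 9.488) or the blended cost exceeds `max_cost` (0.7).
λ defaults to 0.98: appearance dominates, motion vetoes.  Tracks still
unmatched — and all tentative tracks — then enter an IoU round gated at
`max_iou_distance`.  In `iou_only` (default) and `nwd` modes the
cascade collapses to that single round, with cost 1 − IoU or 1 − NWD.
The IoU round admits all unmatched tracks rather than only
once-missed ones: under the linear motion of this setting, predictions
stay reliable through longer gaps, and re-admitting stale tracks
reduces fragmentation at high miss rates.

The default cost mode is `iou_only` because the application provides no
trained appearance model; the appearance path is exercised through the
simulator's synthetic identity-correlated features and any real
feature provider can be plugged in per detection.

Lifecycle: tracks confirm after `n_init = 3` consecutive hits, are
deleted on the first miss while tentative, and after `max_age = 30`
consecutive misses once confirmed.  Identities are assigned once,
sequentially, and never reused.  Only confirmed tracks updated in the
current frame are reported.

NWD similarity: boxes are modelled as 2-D Gaussians with mean at the
centroid and diagonal spread (w/2, h/2); the squared 2-Wasserstein
distance is then the squared Euclidean distance between (cx, cy, w/2,
h/2) vectors, and the similarity is exp(−W₂/C).  C defaults to 12.8,
the standard published constant; it sets the pixel scale at which
similarity decays by 1/e and is configurable because an optimal value
is dataset-dependent.

## Counting

The crossing predicate is the straddle test y1 ≤ line_y ≤ y2,
inclusive at both edges.  The verbal description this implements is
internally inconsistent under top-left coordinates if read literally;
the straddle reading is the only one consistent with the mechanism's
purpose (trigger while the box overlaps the line).  A track whose very
first confirmed observation already straddles the line is counted —
otherwise plants entering the scene on the line would be missed —
and plants that never intersect the line are never counted.  The
line_y default is image mid-height.

Known failure mode, kept measurable rather than patched: an identity
switch while a plant straddles the line counts the switch-born identity
again.  Counting accuracy therefore inherits tracker identity
stability; the tests assert the exact over-count mechanics.

## Evaluation

Detection matching is the standard greedy confidence-ordered protocol:
predictions in descending confidence claim the unmatched ground truth
of highest IoU ≥ 0.5 (threshold configurable).  AP integrates the
exact step precision–recall curve (Σ ΔR·P over rank cuts); the
monotone-envelope variant is available but not the default, since the
definition used here is written as a plain integral.  P and R raise on
zero denominators instead of silently returning 0.

CLEAR-MOT: per-frame correspondences carry over from the previous
frame while both members persist and stay within the IoU gate; the
remainder are matched by Hungarian assignment on 1 − IoU.  An identity
switch is charged when a ground-truth object's matched hypothesis ID
differs from the last hypothesis ID it was ever matched to (so a
switch across an occlusion gap is still a switch).  IDF1 pairs
ground-truth and hypothesis identities one-to-one over whole
trajectories by maximizing per-frame spatial coincidences (IDTP) with
the Hungarian algorithm on the negated overlap-count matrix; this is
exact, verified against exhaustive bijection enumeration in tests.

Because confirmation takes `n_init` frames, the first `n_init − 1`
frames of each ground-truth trajectory are structurally unobservable in
the tracker output.  Tracking metrics are computed against ground truth
with those frames removed (`warmup_aligned_gt`), so they measure
association quality, not the confirmation delay.  Detection metrics use
the unaligned ground truth.

## Simulator

The generator emulates the survey geometry, not its photometry: plants
are boxes scrolling upward at exactly `scroll_speed` px/frame
(default 4), sized uniformly in 24–48 px inside a 640×480 frame over
150 frames, 25 plants per scene — a moderate-density pass in which a
plant is visible for roughly 100 frames and straddles the mid-height
counting line for 7–13 frames, comfortably longer than the 3-frame
confirmation warm-up.  Plants are placed without overlap (unless
occluded pairs are requested) in a strip starting just below the
counting line: the camera starts at the field edge, so every counted
plant's crossing is fully observable.  A plant contributes ground truth
only while its box lies entirely inside the frame.

Corruption models detector failure modes as independent knobs:
per-box Bernoulli misses (`miss_prob`), Gaussian corner jitter
(`jitter_std`), Poisson spurious boxes per frame (`fp_rate`), and
appearance noise on per-plant prototype features (unit-norm, mutually
near-orthogonal via QR when the plant count fits the feature
dimension).  Confidences are uniform in `conf_range` and carry no
signal — deliberately, so confidence filtering and NMS are exercised
without giving the tracker an oracle.  All draws flow from one seeded
generator in a fixed documented order; a scene is a pure function of
its config.

What the simulator does not model: photometric effects (brightness,
blur — these act through the miss/jitter knobs only), leaf motion,
perspective and lens distortion, detector confidence correlated with
difficulty, and correlated (burst) misses.  Passing tests therefore
demonstrate the correctness and failure modes of the tracking,
counting and evaluation machinery under the stated geometry — not
field-level detector performance.

## Acceptance problem sizes

The acceptance script uses 20 zero-noise scenes (25 plants, 150 frames
each, ~38k ground-truth boxes total) for the recovery check and
10 seeds × 4 miss probabilities for the degradation sweep, isolating
the miss factor with the other corruption knobs at zero — under joint
corruption, jitter-born over-counts and miss-born under-counts can
cancel in ER and mask the trend that the sweep is meant to expose.
The sweep's medians are reported alongside boolean monotonicity flags.

## Known limitations

* Counting assumes plants cross the line at most once per pass
  (monotone camera motion); a hovering or reversing platform would
  re-expose counted identities, which the counted-ID set handles, but
  uncounted plants drifting back below the line are not re-armed.
* The IoU fallback admits arbitrarily stale tracks; in scenes with
  dense identical-size plants this can trade identity switches for
  fragmentation.
* The greedy detection-matching protocol is not globally TP-maximal on
  adversarially overlapping instances (it is the field's standard and
  provably optimal when ground truths are separated at the gate).
* MOTA can be negative with many false positives; this is inherent to
  the metric, not clamped.
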
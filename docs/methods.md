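# Methods

This note documents the models implemented in `cagewatch`, the parameter
choices that matter, the numerical conventions, and what the synthetic
fixtures do and do not demonstrate.

## Background elimination

The detector assumes a static camera and a scene whose appearance is
dominated by a fixed background; an animal is whatever deviates from it.

**Background synthesis.** Every `stride`-th frame (default 10) is resized to
`target_size` (default 1280×720) and Gaussian-blurred (5×5 kernel,
σ = 0.3·((k−1)/2 − 1) + 0.8 ≈ 1.1, the standard kernel-to-sigma relation) to
suppress sensor noise before order statistics are taken. Sampled frames are
partitioned into consecutive groups of `group_size` (default 120 ≈ 80 s of
video at 15 fps sampled at stride 10); per group, per pixel, per channel the
70th percentile forms a *sub-background*. The percentile uses the *lower*
interpolation rule (largest data value at or below the requested rank) so
8-bit outputs never interpolate between intensity levels. The final
background is the per-pixel median across sub-backgrounds, rounded to
8-bit. The rationale for the 70th percentile: an animal occupying a pixel in
under ~30% of a group's frames cannot displace that pixel's background
value. A final partial group is kept — discarding data from short videos
would silently change results.

**Foreground extraction.** Each frame is compared against a single-component
per-pixel Gaussian model whose means are the synthesized background and
whose statistics are frozen during inference (no learning — the background
is already the best static estimate, and adapting online would absorb a
resting animal twice over). A pixel is foreground when its squared RGB
distance exceeds `var_threshold · var_init` (defaults 16 and 15, the
conventional Gaussian-mixture segmentation settings; the product 240
corresponds to ≈ 9 intensity levels per channel). Shadow suppression is on
by default: a pixel whose observed colour is a uniformly dimmed copy of the
background (brightness ratio in [0.5, 1], chromatic residual within the
same tolerance) is reclassified as background. Dark fur still segments
because its chroma differs from the background's.

**Refinement.** Morphological closing then opening with a 5×5 disk (2 and 1
iterations; an iteration count of *n* means *n* dilations followed by *n*
erosions, so the compound operation grows with *n*), 8-connected labelling,
convex hull per component, iterative merging of any two hulls with positive
shared area (touching suffices for degenerate zero-area hulls) until a
fixpoint, filling each hull, and dropping regions below `min_area` (default
2000 px² at 1280×720, ≈ 0.2% of the frame, scaled proportionally to other
resolutions by `default_min_area`). Morphology and area defaults are this
package's choices, exposed in `BEConfig`.

**Known failure modes**, reproduced by the fixtures: a subject that never
moves is absorbed into the background and missed almost entirely; two
animals close enough for their hulls to overlap merge into one detection;
global overexposure floods the foreground mask.

## Tracking

State per target is centroid position and per-frame velocity
`(cx, cy, vx, vy)`; box width/height are carried verbatim from the last
matched detection rather than filtered, since box size changes mostly with
posture, not smooth motion. Constant-velocity transition with
discrete-white-noise-acceleration process covariance (intensity
`process_noise`, default 1 px/frame²); position-only measurements with noise
std `measurement_noise` (default 10 px — detection centroids of a deforming
body jitter far more than the sensor). New tracks start at the detection
centroid with zero velocity and inflated velocity variance (std 50
px/frame); birth is immediate, with no confirmation window.

Association is Hungarian assignment on Euclidean centroid distance; pairs
beyond `gate_distance` (default 150 px at 1280×720, roughly one body length)
are discarded. An unmatched track coasts: the predicted centroid with the
carried box size is emitted as a synthetic detection (flagged `coasted`,
keeping the last matched score so threshold sweeps do not silently drop
fill-ins) for at most `coast_limit` = 20 consecutive frames, after which the
track dies and a re-appearing animal receives a fresh identity. Coasted
boxes are included in the scored output — that is what makes recall
improve after tracking, and equally what propagates a persistent false
positive for up to 20 frames after it disappears.

## Evaluation

Matching is greedy in descending confidence, one-to-one per frame, with a
tie on IoU broken toward the lower ground-truth index — the standard
detection-benchmark matcher, deterministic and order-free. A detection that
matches no scored ground truth but overlaps an ignored instance at IoU ≥
threshold is discarded from scoring entirely (ignore regions may absorb any
number of detections). Counts are summed over all frames of a video before
metrics are computed (micro aggregation): per-frame metrics would be
undefined on frames without ground truth and bias any average. 0/0 metrics
propagate as missing and are excluded from medians rather than coerced.

Per-individual scoring restricts ground truth to one identity; detections
matched to *other* identities are removed from that individual's
false-positive pool, while fully unmatched detections count against every
individual (they cannot be attributed).

The sweep evaluates thresholds 0.50–0.95 (step 0.05) per video, takes
medians across videos, and selects the argmax of median F1 (ties to the
lower threshold; "maximise precision and recall" needs a scalarization and
the F1 harmonic mean is the natural one already in use). Detectors without
confidences (BE emits score 1.0) pass every threshold unchanged.

## Statistics

The Friedman statistic is the classic
`χ² = 12/(n·k·(k+1))·ΣR_j² − 3n(k+1)` on within-subject average ranks,
referenced to χ² with k−1 dof. The tie-corrected variant is deliberately
not used: fully tied data should report χ² = 0, p = 1 (no evidence of
difference), not an indeterminate value. The χ² reference is an
approximation; it is accurate in the rejection region but can overstate
significance moderately for k = 3 with n ≈ 10 at large p, which the test
suite quantifies against a permutation null.

Wilcoxon signed-rank: zero differences dropped (the original treatment),
ties mid-ranked, statistic T⁺ = sum of ranks of positive differences of
(first − second). The two-sided p is exact for n ≤ 25 — computed by dynamic
programming over the doubled-rank distribution, identical to enumerating
all 2ⁿ sign patterns; the distribution is symmetric about half the rank
total, so the two-sided tail is well defined even with ties. Beyond n = 25
a normal approximation with tie and continuity corrections is used.
T⁺ = 0 means the second-listed sample never fell below the first.

Benjamini–Hochberg adjusted p-values follow the step-up formula
`adj_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, applied within the family of
all pairwise comparisons of one metric. Note the adjusted-p *mapping* is
not idempotent (re-adjusting already-adjusted values can increase them);
the rejection decisions are what the procedure controls.

## Synthetic scenes

The generator emulates the challenges of home-cage footage: single or
paired moving subjects, occlusion by railing bars and enrichment objects,
semi-transparent reflections, overexposure episodes, Gaussian sensor noise
(σ = 2 intensity levels), and a moving animal inside a marked
neighbouring-cage region annotated with `ignore=True`. Subjects are
textured deformable two-ellipse bodies on waypoint paths at constant speed;
body eccentricity pulses with an 8% amplitude over a 45-frame period.
During a stationary episode both position and deformation freeze — a
resting animal is still, which is exactly the condition under which
background subtraction fails. Ground truth is the tight pixel bounds of the
rendered body *before* occluder overdraw, matching the annotation
convention that a box covers all body parts even when occluded.

Default fixture resolution is 320×180 — a scale-preserving quarter of the
1280×720 cage-camera format — with 300 frames per fixture (20 s at 15 fps),
sized so the full suite and the acceptance script each run in well under
their budgets on one CPU. All geometry is computed on the integer pixel
grid and all randomness comes from `numpy.random.default_rng(seed)`, so
fixtures are byte-identical across platforms.

**What passing these fixtures does not show.** Subjects are high-contrast
rigid-ish blobs; real macaques deform, self-occlude, match the background
locally (fur against wooden perches), and interact. The fixtures therefore
validate the *mechanics* of each algorithm (percentile background
synthesis, coasting limits, ignore handling, threshold selection), not
field performance on real footage. Camera motion, zoom, and photometric
drift are out of scope.

## Numerical conventions

- Boxes are 0-based, half-open `[x_min, x_max) × [y_min, y_max)`; a VIA
  rectangle `(x, y, w, h)` maps to `(x, y, x+w, y+h)`.
- Interchange CSV floats carry 6 decimals; integers round-trip exactly.
- Degenerate convex hulls (collinear components) fall back to zero-area
  geometries and are merged by intersection rather than shared area.
- Empty inputs: an empty foreground mask refines to an empty cluster list;
  an empty detection stream tracks to an empty stream; 0/0 metrics are
  undefined, not zero.
- The Kalman update symmetrizes the covariance after each step to keep it
  positive-semidefinite against round-off.
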
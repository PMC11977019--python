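# cagewatch

Detection, tracking and evaluation toolkit for video monitoring of macaques
in home cages.

Continuous video of laboratory primates is the raw material for welfare
assessment and behaviour studies, but turning footage into per-animal
positions requires a detector, a tracker to maintain identity through missed
detections, and a scoring harness to compare detectors fairly. `cagewatch`
provides that machinery for the common single- or pair-housed cage setup:

- **Background elimination (BE)** — a training-free detector. A static
  background is synthesized from every 10th frame (groups of 120 frames,
  per-pixel per-channel 70th percentile, median across groups); each frame
  is then compared to frozen per-pixel Gaussian background statistics,
  the foreground is cleaned by morphology, overlapping convex hulls are
  merged, small clusters are dropped, and a tight bounding box is placed
  around each remaining cluster.
- **Tracking** — one constant-velocity Kalman filter per animal over the
  detection centroid `(cx, cy, vx, vy)`, Hungarian assignment of predicted
  to detected centroids, and *coasting*: when an animal goes undetected the
  predicted box (last known size) is emitted for up to 20 consecutive
  frames before the track is terminated.
- **Evaluation** — IoU-based scoring (`IoU = |A ∩ B| / |A ∪ B|`, a detection
  is a true positive at IoU ≥ 0.50), with precision `TP/(TP+FP)`, recall
  `TP/(TP+FN)` and `F1 = 2PR/(P+R)` accumulated per video and per
  individual. Animals in neighbouring cages carry an ignore flag: detecting
  them earns no credit and missing them costs nothing. A confidence sweep
  from 0.50 to 0.95 in 0.05 steps selects the score threshold maximising
  median F1 across videos.
- **Model comparison** — Friedman test across ≥3 detectors on paired
  subjects, pairwise Wilcoxon signed-rank tests (exact two-sided p for
  n ≤ 25), and Benjamini–Hochberg correction per metric family.
- **Synthetic scenes** — a seeded generator of home-cage-like video with
  exact ground truth: textured deformable subjects on waypoint paths,
  railing/enrichment occluders, glass reflections, overexposure episodes,
  sensor noise, and ignored neighbouring-cage animals. Identical config and
  seed reproduce byte-identical frames on any platform.

Ground truth is read from VIA 2.x annotation projects (polygon and
rectangle regions); detections travel in a simple CSV interchange format so
any external detector's output can be tracked and scored.

## Worked example

Simulate a clean scene, run the background-elimination detector and score it:

```bash
cagewatch simulate --fixture single_clean --frame-size 160 90 --n-frames 80 \
    --out-video scene.tif --out-gt gt.json
cagewatch detect-be --video scene.tif --out dets.csv \
    --target-size 160 90 --group-size 8
cagewatch evaluate --dets dets.csv --gt gt.json --out report.csv
```

The evaluation prints one row per video:

```
   video_id instance_id  tp  fp  fn  precision  recall   f1
single_clean        all  80   0   0        1.0     1.0  1.0
```

meaning all 80 ground-truth boxes were matched at IoU ≥ 0.5 with no spurious
detections. Tracking a stream with a 5-frame detection gap fills the gap by
coasting:

```bash
cagewatch simulate --fixture dropout_gap5 --out-gt gt.json --out-dets dets.csv
cagewatch track --in dets.csv --out tracked.csv
# -> 150 rows (5 coasted) -> tracked.csv
```

and re-evaluating `tracked.csv` against `gt.json` raises recall from 0.967
to 1.0 — the before/after comparison that `cagewatch compare` can then test
across videos with Wilcoxon statistics.

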
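"""Detection scoring against ground truth.

A detection is a true positive when its IoU with an unmatched ground-truth
box reaches 0.50 (Intersection over Union: overlap area / union area).
Matching is greedy in descending confidence, one-to-one per frame.  Animals
flagged ``ignore`` (neighbouring, non-focal cages) grant no credit and incur
no penalty: detections overlapping them are discarded from scoring and
missing them is not a false negative.

Counts are accumulated over all frames of a video before precision, recall
and F1 are computed (micro aggregation), per video and — where ground truth
carries instance identities — per individual.  A confidence-threshold sweep
from 0.50 to 0.95 in 0.05 steps reports median precision/recall/F1 across
videos and selects the threshold maximising median F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BoundingBox, Detection, GroundTruthInstance, ValidationError

__all__ = [
    "MatchCounts",
    "MetricsRecord",
    "SweepPoint",
    "FrameMatch",
    "iou",
    "match_frame",
    "compute_metrics",
    "evaluate_video",
    "evaluate_dataset",
    "threshold_sweep",
    "compare_before_after",
    "DEFAULT_SWEEP_THRESHOLDS",
]

DEFAULT_SWEEP_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsRecord:
    """Precision/recall/F1 for one (video, instance) scope; ``None`` marks an
    undefined (0/0) metric, which is excluded from medians downstream."""

    video_id: str
    instance_id: str  # "all" for the pooled record
    counts: MatchCounts
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class SweepPoint:
    threshold: float
    median_precision: float | None
    median_recall: float | None
    median_f1: float | None


@dataclass(frozen=True)
class FrameMatch:
    """Outcome of matching one frame: aggregate counts plus assignments
    (detection index -> ground-truth index) and indices of detections
    absorbed by ignore regions."""

    counts: MatchCounts
    assignments: tuple[tuple[int, int], ...]
    ignored_detections: tuple[int, ...]
    unmatched_detections: tuple[int, ...]
    unmatched_gt: tuple[int, ...]


def match_frame(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthInstance],
    iou_threshold: float = 0.50,
) -> FrameMatch:
    """Greedy score-ordered one-to-one matching of one frame's detections to
    its ground truth.

    Each detection, in descending confidence, takes the highest-IoU unmatched
    non-ignored ground truth at IoU >= threshold (tie: lower ground-truth
    index).  A detection that finds no such match but overlaps an ignored
    instance at IoU >= threshold is discarded from scoring; the remainder are
    false positives.  Unmatched non-ignored ground truth are false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    scored_gt = [i for i, g in enumerate(gts) if not g.ignore]
    ignored_gt = [i for i, g in enumerate(gts) if g.ignore]
    taken: set[int] = set()
    assignments: list[tuple[int, int]] = []
    ignored_dets: list[int] = []
    fp_dets: list[int] = []

    for di in order:
        best_gt, best_iou = None, iou_threshold
        for gi in scored_gt:
            if gi in taken:
                continue
            v = iou(dets[di].box, gts[gi].box)
            if v > best_iou or (v == best_iou and v >= iou_threshold and best_gt is None):
                best_gt, best_iou = gi, v
        if best_gt is not None:
            taken.add(best_gt)
            assignments.append((di, best_gt))
            continue
        # ignore-region absorption: no one-to-one bookkeeping needed
        if any(
            iou(dets[di].box, gts[gi].box) >= iou_threshold for gi in ignored_gt
        ):
            ignored_dets.append(di)
        else:
            fp_dets.append(di)

    unmatched_gt = tuple(gi for gi in scored_gt if gi not in taken)
    counts = MatchCounts(
        tp=len(assignments), fp=len(fp_dets), fn=len(unmatched_gt)
    )
    return FrameMatch(
        counts=counts,
        assignments=tuple(assignments),
        ignored_detections=tuple(ignored_dets),
        unmatched_detections=tuple(fp_dets),
        unmatched_gt=unmatched_gt,
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    counts: MatchCounts, video_id: str = "video", instance_id: str = "all"
) -> MetricsRecord:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    any 0/0 yields ``None`` (undefined), excluded from medians."""
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None if (precision is None or recall is None) else 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsRecord(video_id, instance_id, counts, precision, recall, f1)


def evaluate_video(
    dets_by_frame: Mapping[int, Sequence[Detection]],
    gts_by_frame: Mapping[int, Sequence[GroundTruthInstance]],
    iou_threshold: float = 0.50,
    score_threshold: float = 0.0,
    video_id: str = "video",
    per_individual: bool = False,
) -> list[MetricsRecord]:
    """Score one video: counts accumulated over all frames, metrics computed
    once (micro aggregation).  With ``per_individual``, additionally returns
    one record per ground-truth instance id, where that individual's false
    positives are the detections matched to no individual at all."""
    pooled = MatchCounts()
    per_id_tp: dict[str, int] = {}
    per_id_fn: dict[str, int] = {}
    shared_fp = 0

    frames = sorted(set(dets_by_frame) | set(gts_by_frame))
    for fi in frames:
        dets = [
            d for d in dets_by_frame.get(fi, []) if d.score >= score_threshold
        ]
        gts = list(gts_by_frame.get(fi, []))
        fm = match_frame(dets, gts, iou_threshold)
        pooled = pooled + fm.counts
        shared_fp += fm.counts.fp
        for _, gi in fm.assignments:
            per_id_tp[gts[gi].instance_id] = per_id_tp.get(gts[gi].instance_id, 0) + 1
        for gi in fm.unmatched_gt:
            per_id_fn[gts[gi].instance_id] = per_id_fn.get(gts[gi].instance_id, 0) + 1

    records = [compute_metrics(pooled, video_id, "all")]
    if per_individual:
        for iid in sorted(set(per_id_tp) | set(per_id_fn)):
            counts = MatchCounts(
                tp=per_id_tp.get(iid, 0), fp=shared_fp, fn=per_id_fn.get(iid, 0)
            )
            records.append(compute_metrics(counts, video_id, iid))
    return records


def evaluate_dataset(
    dets: Mapping[str, Mapping[int, Sequence[Detection]]],
    gts: Mapping[str, Mapping[int, Sequence[GroundTruthInstance]]],
    iou_threshold: float = 0.50,
    score_threshold: float = 0.0,
    per_individual: bool = False,
) -> list[MetricsRecord]:
    """Score several videos; detections for a video absent from the ground
    truth are an error (a silent drop would inflate precision)."""
    missing = sorted(set(dets) - set(gts))
    if missing:
        raise ValidationError(
            f"videos present in detections but absent from ground truth: {missing}"
        )
    records: list[MetricsRecord] = []
    for video_id in sorted(gts):
        records.extend(
            evaluate_video(
                dets.get(video_id, {}),
                gts[video_id],
                iou_threshold,
                score_threshold,
                video_id,
                per_individual,
            )
        )
    return records


def _median(values: list[float]) -> float | None:
    return float(np.median(values)) if values else None


def threshold_sweep(
    dets: Mapping[str, Mapping[int, Sequence[Detection]]],
    gts: Mapping[str, Mapping[int, Sequence[GroundTruthInstance]]],
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
    iou_threshold: float = 0.50,
) -> tuple[list[SweepPoint], float]:
    """Confidence-threshold sweep: for each threshold, score every video and
    take the median precision/recall/F1 across videos (undefined metrics
    excluded).  The selected threshold maximises median F1; ties go to the
    lower threshold."""
    points: list[SweepPoint] = []
    for t in thresholds:
        records = evaluate_dataset(dets, gts, iou_threshold, score_threshold=t)
        points.append(
            SweepPoint(
                threshold=t,
                median_precision=_median(
                    [r.precision for r in records if r.precision is not None]
                ),
                median_recall=_median(
                    [r.recall for r in records if r.recall is not None]
                ),
                median_f1=_median([r.f1 for r in records if r.f1 is not None]),
            )
        )
    best = max(
        points,
        key=lambda p: (p.median_f1 if p.median_f1 is not None else -1.0, -p.threshold),
    )
    return points, best.threshold


def compare_before_after(
    dets_a: Mapping[str, Mapping[int, Sequence[Detection]]],
    dets_b: Mapping[str, Mapping[int, Sequence[Detection]]],
    gts: Mapping[str, Mapping[int, Sequence[GroundTruthInstance]]],
    iou_threshold: float = 0.50,
    score_threshold: float = 0.0,
    labels: tuple[str, str] = ("before", "after"),
) -> pd.DataFrame:
    """Per-video metrics for two conditions (e.g. before/after tracking),
    aligned by video for paired testing.  Columns:
    video_id, condition, precision, recall, f1, tp, fp, fn."""
    if set(dets_a) != set(dets_b):
        raise ValidationError(
            f"video sets differ between conditions: "
            f"{sorted(set(dets_a) ^ set(dets_b))}"
        )
    rows = []
    for label, dets in zip(labels, (dets_a, dets_b)):
        for rec in evaluate_dataset(dets, gts, iou_threshold, score_threshold):
            rows.append(
                {
                    "video_id": rec.video_id,
                    "condition": label,
                    "precision": rec.precision,
                    "recall": rec.recall,
                    "f1": rec.f1,
                    "tp": rec.counts.tp,
                    "fp": rec.counts.fp,
                    "fn": rec.counts.fn,
                }
            )
    return pd.DataFrame(rows)


def records_to_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Metrics records as a tidy DataFrame (one row per scope)."""
    return pd.DataFrame(
        [
            {
                "video_id": r.video_id,
                "instance_id": r.instance_id,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
            }
            for r in records
        ]
    )
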
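"""IoU, frame matching with ignore regions, metrics, sweeps, paired tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagewatch.evaluation import (
    DEFAULT_SWEEP_THRESHOLDS,
    MatchCounts,
    compare_before_after,
    compute_metrics,
    evaluate_dataset,
    evaluate_video,
    iou,
    match_frame,
    threshold_sweep,
)
from cagewatch.io_formats import (
    BoundingBox,
    Detection,
    GroundTruthInstance,
    ValidationError,
)


def pixel_iou_oracle(a: BoundingBox, b: BoundingBox) -> float:
    """Integer-pixel enumeration: count unit pixels in each box and both."""
    ax = set(range(int(a.x_min), int(a.x_max)))
    ay = set(range(int(a.y_min), int(a.y_max)))
    bx = set(range(int(b.x_min), int(b.x_max)))
    by = set(range(int(b.y_min), int(b.y_max)))
    pa = {(x, y) for x in ax for y in ay}
    pb = {(x, y) for x in bx for y in by}
    union = len(pa | pb)
    return len(pa & pb) / union if union else 0.0


def _gt(frame, box, iid="A", ignore=False):
    return GroundTruthInstance(
        frame_index=frame, instance_id=iid, box=BoundingBox(*box), ignore=ignore
    )


def _det(frame, box, score=1.0):
    return Detection(frame_index=frame, box=BoundingBox(*box), score=score)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap(self):
        v = iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10))
        assert v == pytest.approx(50 / 150)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_pixel_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            x0, y0, x1, y1 = *rng.integers(0, 15, 2), *rng.integers(16, 30, 2)
            a = BoundingBox(x0, y0, x1, y1)
            u0, v0, u1, v1 = *rng.integers(0, 15, 2), *rng.integers(16, 30, 2)
            b = BoundingBox(u0, v0, u1, v1)
            assert iou(a, b) == pytest.approx(pixel_iou_oracle(a, b), abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(0, 100) for _ in range(4)]),
        st.tuples(*[st.floats(0, 100) for _ in range(4)]),
    )
    def test_symmetry_and_bounds(self, p, q):
        try:
            a = BoundingBox(min(p[0], p[2]), min(p[1], p[3]),
                            max(p[0], p[2]), max(p[1], p[3]))
            b = BoundingBox(min(q[0], q[2]), min(q[1], q[3]),
                            max(q[0], q[2]), max(q[1], q[3]))
        except ValidationError:
            return
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)


class TestMatchFrame:
    def test_exact_hit(self):
        fm = match_frame([_det(0, (0, 0, 10, 10))], [_gt(0, (0, 0, 10, 10))])
        assert fm.counts == MatchCounts(tp=1, fp=0, fn=0)

    def test_false_positive_and_false_negative(self):
        assert match_frame([_det(0, (0, 0, 10, 10))], []).counts == MatchCounts(0, 1, 0)
        assert match_frame([], [_gt(0, (0, 0, 10, 10))]).counts == MatchCounts(0, 0, 1)

    def test_duplicate_detections_one_to_one(self):
        gt = [_gt(0, (0, 0, 10, 10))]
        dets = [_det(0, (0, 0, 10, 10), 0.8), _det(0, (1, 0, 11, 10), 0.9)]
        fm = match_frame(dets, gt)
        assert fm.counts == MatchCounts(tp=1, fp=1, fn=0)
        assert fm.assignments == ((1, 0),)  # higher score matched first

    def test_ignored_gt_grants_no_credit_no_penalty(self):
        gt = [_gt(0, (0, 0, 10, 10), iid="neighbour", ignore=True)]
        fm = match_frame([_det(0, (0, 0, 10, 9))], gt)  # IoU 0.9 on ignored
        assert fm.counts == MatchCounts(tp=0, fp=0, fn=0)
        assert fm.ignored_detections == (0,)

    def test_conservation_invariants(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            gts, dets = [], []
            for i in range(rng.integers(0, 6)):
                x, y = rng.uniform(0, 80, 2)
                gts.append(_gt(0, (x, y, x + 20, y + 20), iid=f"g{i}",
                               ignore=bool(rng.random() < 0.3)))
            for _ in range(rng.integers(0, 6)):
                x, y = rng.uniform(0, 80, 2)
                dets.append(_det(0, (x, y, x + 20, y + 20), rng.uniform()))
            fm = match_frame(dets, gts)
            n_scored = sum(not g.ignore for g in gts)
            assert fm.counts.tp + fm.counts.fn == n_scored
            assert fm.counts.tp + fm.counts.fp + len(fm.ignored_detections) == len(dets)


class TestComputeMetrics:
    def test_basic(self):
        rec = compute_metrics(MatchCounts(tp=90, fp=10, fn=10))
        assert rec.precision == 0.9 and rec.recall == 0.9 and rec.f1 == 0.9

    def test_harmonic_mean_worked_examples(self):
        # printed precision/recall pairs with their published-style F1 values
        cases = [
            (0.89, 0.86, 0.87),
            (0.92, 0.82, 0.87),
            (0.91, 0.89, 0.90),
            (0.90, 0.82, 0.86),
        ]
        for p, r, f1_expected in cases:
            f1 = 2 * p * r / (p + r)
            assert round(f1, 2) == f1_expected

    def test_zero_counts_undefined(self):
        rec = compute_metrics(MatchCounts(0, 0, 0))
        assert rec.precision is None and rec.recall is None and rec.f1 is None

    def test_f1_consistency_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            rec = compute_metrics(
                MatchCounts(*(int(v) for v in rng.integers(0, 30, 3)))
            )
            if rec.f1 and rec.precision and rec.recall:
                assert rec.f1 == pytest.approx(
                    2 * rec.precision * rec.recall / (rec.precision + rec.recall),
                    abs=1e-12,
                )


class TestEvaluateVideo:
    def _perfect(self, n=100):
        gts = {f: [_gt(f, (10 + f, 20, 40 + f, 60))] for f in range(n)}
        dets = {f: [_det(f, (10 + f, 20, 40 + f, 60))] for f in range(n)}
        return dets, gts

    def test_perfect_detections(self):
        dets, gts = self._perfect()
        rec = evaluate_video(dets, gts)[0]
        assert rec.precision == rec.recall == rec.f1 == 1.0

    def test_ten_percent_deleted_gives_recall_09(self):
        dets, gts = self._perfect(100)
        for f in range(0, 100, 10):  # exactly 10% of boxes removed
            dets[f] = []
        rec = evaluate_video(dets, gts)[0]
        assert rec.recall == pytest.approx(0.9)
        assert rec.precision == 1.0

    def test_matches_bruteforce_per_frame_recount(self):
        rng = np.random.default_rng(21)
        gts, dets = {}, {}
        for f in range(40):
            gts[f] = [
                _gt(f, (x, y, x + 25, y + 25), iid=f"g{i}")
                for i, (x, y) in enumerate(rng.uniform(0, 100, (2, 2)))
            ]
            dets[f] = [
                _det(f, (x + rng.uniform(-4, 4), y, x + 25, y + 25), rng.uniform())
                for x, y in rng.uniform(0, 100, (3, 2))
            ]
        rec = evaluate_video(dets, gts)[0]
        total = MatchCounts()
        for f in range(40):
            total = total + match_frame(dets[f], gts[f]).counts
        assert rec.counts == total

    def test_per_individual_scoping(self, suite):
        bundle = suite["paired_overlap"]
        dets = {
            f: [
                Detection(frame_index=f, box=g.box, score=1.0)
                for g in gs
                if g.instance_id == "macaque_A"  # drop all of B's boxes
            ]
            for f, gs in bundle.gt.items()
        }
        records = evaluate_video(dets, bundle.gt, per_individual=True,
                                 video_id="paired_overlap")
        by_id = {r.instance_id: r for r in records}
        assert set(by_id) == {"all", "macaque_A", "macaque_B"}
        assert by_id["macaque_A"].recall > 0.95
        assert by_id["macaque_B"].recall is None or by_id["macaque_B"].recall < 0.3

    def test_unknown_video_in_detections_is_error(self):
        dets, gts = self._perfect(5)
        with pytest.raises(ValidationError, match="ghost"):
            evaluate_dataset({"ghost": dets}, {"real": gts})


class TestThresholdSweep:
    def test_constant_scores_flat_sweep(self):
        gts = {f: [_gt(f, (0, 0, 20, 20))] for f in range(20)}
        dets = {f: [_det(f, (0, 0, 20, 20), score=1.0)] for f in range(20)}
        points, selected = threshold_sweep({"v": dets}, {"v": gts})
        assert selected == 0.50
        assert len({(p.median_precision, p.median_recall) for p in points}) == 1

    def test_calibrated_scores_select_separation_point(self):
        # TPs scored above 0.7, FPs below: precision climbs to 1 at 0.70
        rng = np.random.default_rng(5)
        gts, dets = {}, {}
        for f in range(50):
            gts[f] = [_gt(f, (30, 30, 60, 60))]
            frame_dets = [_det(f, (30, 30, 60, 60), float(rng.uniform(0.72, 1.0)))]
            if f % 2:
                frame_dets.append(
                    _det(f, (100, 100, 130, 130), float(rng.uniform(0.5, 0.68)))
                )
            dets[f] = frame_dets
        points, selected = threshold_sweep({"v": dets}, {"v": gts})
        assert selected == 0.70  # full precision reached, recall still intact
        precisions = [p.median_precision for p in points if p.threshold <= 0.7]
        assert precisions == sorted(precisions) and precisions[-1] == 1.0
        low = [p.median_recall for p in points if p.threshold <= 0.70]
        assert set(low) == {1.0}  # no true positive scored below 0.72

    def test_empty_top_bucket_undefined(self):
        gts = {0: [_gt(0, (0, 0, 20, 20))]}
        dets = {0: [_det(0, (0, 0, 20, 20), score=0.6)]}
        points, _ = threshold_sweep({"v": dets}, {"v": gts})
        top = next(p for p in points if p.threshold == 0.95)
        assert top.median_precision is None
        assert top.median_recall == 0.0

    def test_threshold_grid(self):
        assert DEFAULT_SWEEP_THRESHOLDS[0] == 0.50
        assert DEFAULT_SWEEP_THRESHOLDS[-1] == 0.95
        steps = np.diff(DEFAULT_SWEEP_THRESHOLDS)
        assert np.allclose(steps, 0.05)


class TestCompareBeforeAfter:
    def test_identical_conditions_zero_differences(self):
        gts = {f: [_gt(f, (0, 0, 20, 20))] for f in range(10)}
        dets = {f: [_det(f, (0, 0, 20, 20))] for f in range(10)}
        table = compare_before_after({"v": dets}, {"v": dets}, {"v": gts})
        wide = table.pivot(index="video_id", columns="condition", values="f1")
        assert (wide["before"] == wide["after"]).all()

    def test_video_set_mismatch_is_error(self):
        gts = {0: [_gt(0, (0, 0, 20, 20))]}
        dets = {0: [_det(0, (0, 0, 20, 20))]}
        with pytest.raises(ValidationError):
            compare_before_after({"a": dets}, {"b": dets}, {"a": gts, "b": gts})
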
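"""Multi-target tracking: constant-velocity Kalman filtering per target,
Hungarian association of predicted centroids to detections, and coasting.

Each target is tracked by the centroid of its detection (mask centroid where
a mask is available, box centre otherwise) with a 4-dimensional state
``(cx, cy, vx, vy)`` — position in pixels, velocity in pixels/frame.  When a
target goes undetected, the filter keeps predicting its position and the
tracker emits a synthetic "coasted" box of the last known size at the
predicted centroid, for at most ``coast_limit`` consecutive frames (default
20), after which the track is terminated and a re-appearing animal receives
a fresh identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import BoundingBox, Detection, ValidationError

__all__ = [
    "Track",
    "TrackerConfig",
    "centroid",
    "kalman_predict",
    "kalman_update",
    "hungarian_assign",
    "tracker_step",
    "run_tracker",
]

# constant-velocity transition and position-only measurement model, dt = 1
_F = np.array(
    [[1.0, 0.0, 1.0, 0.0],
     [0.0, 1.0, 0.0, 1.0],
     [0.0, 0.0, 1.0, 0.0],
     [0.0, 0.0, 0.0, 1.0]]
)
_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


def _process_noise_cov(q: float) -> np.ndarray:
    """Discrete white-noise-acceleration covariance for dt = 1, intensity q
    (px/frame^2 squared), independent per axis."""
    g = np.array([[0.5, 0.0], [0.0, 0.5], [1.0, 0.0], [0.0, 1.0]])
    return q * g @ g.T


@dataclass(frozen=True)
class TrackerConfig:
    coast_limit: int = 20  # frames a track survives without a match
    gate_distance: float = 150.0  # px, association cutoff at 1280x720
    process_noise: float = 1.0  # accel noise intensity, px/frame^2
    measurement_noise: float = 10.0  # centroid noise std, px
    initial_velocity_std: float = 50.0  # px/frame, uncertainty at track birth

    def __post_init__(self) -> None:
        if self.coast_limit < 0:
            raise ValidationError("coast_limit must be >= 0")
        if self.gate_distance <= 0:
            raise ValidationError("gate_distance must be > 0")


@dataclass
class Track:
    """One target's filter state, carried box size, and coast counter."""

    track_id: int
    state: np.ndarray  # (4,) cx, cy, vx, vy
    covariance: np.ndarray  # 4x4 SPD
    last_box_size: tuple[float, float]  # (width, height) px
    last_score: float = 1.0
    frames_since_detection: int = 0
    alive: bool = True

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.state[0]), float(self.state[1]))


def centroid(detection: Detection) -> tuple[float, float]:
    """Geometric centre of a detection: mean of mask pixel coordinates when a
    mask is present, box centre otherwise."""
    if detection.mask is not None:
        rows, cols = np.nonzero(detection.mask)
        if rows.size:
            return (float(cols.mean()), float(rows.mean()))
    return detection.box.center


def new_track(
    track_id: int, detection: Detection, config: TrackerConfig
) -> Track:
    """Start a track on an unmatched detection: zero initial velocity with
    inflated velocity covariance."""
    cx, cy = centroid(detection)
    r2 = config.measurement_noise**2
    v2 = config.initial_velocity_std**2
    return Track(
        track_id=track_id,
        state=np.array([cx, cy, 0.0, 0.0]),
        covariance=np.diag([r2, r2, v2, v2]),
        last_box_size=(detection.box.width, detection.box.height),
        last_score=detection.score,
    )


def kalman_predict(track: Track, config: TrackerConfig) -> Track:
    """One-frame constant-velocity prediction: position advances by velocity,
    covariance grows by F P F' + Q."""
    state = _F @ track.state
    cov = _F @ track.covariance @ _F.T + _process_noise_cov(config.process_noise)
    return replace(track, state=state, covariance=cov)


def kalman_update(
    track: Track, measurement: tuple[float, float], config: TrackerConfig
) -> Track:
    """Standard Kalman measurement update with the detection centroid."""
    z = np.asarray(measurement, float)
    r = config.measurement_noise**2 * np.eye(2)
    innovation = z - _H @ track.state
    s = _H @ track.covariance @ _H.T + r
    gain = track.covariance @ _H.T @ np.linalg.inv(s)
    state = track.state + gain @ innovation
    cov = (np.eye(4) - gain @ _H) @ track.covariance
    cov = (cov + cov.T) / 2.0  # keep symmetric against round-off
    return replace(track, state=state, covariance=cov)


def hungarian_assign(cost: np.ndarray) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment minimizing total cost on an n x m matrix
    of finite nonnegative distances; returns min(n, m) (row, col) pairs."""
    cost = np.asarray(cost, float)
    if cost.size == 0:
        return []
    if np.isnan(cost).any():
        raise ValidationError("cost matrix contains NaN")
    if (cost < 0).any():
        raise ValidationError("cost matrix contains negative entries")
    rows, cols = linear_sum_assignment(cost)
    return list(zip(rows.tolist(), cols.tolist()))


def _coasted_detection(track: Track, frame_index: int, video_id: str) -> Detection:
    cx, cy = track.position
    w, h = track.last_box_size
    return Detection(
        frame_index=frame_index,
        box=BoundingBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0),
        score=track.last_score,
        track_id=track.track_id,
        coasted=True,
        video_id=video_id,
    )


def tracker_step(
    tracks: list[Track],
    frame_detections: Sequence[Detection],
    config: TrackerConfig,
    frame_index: int,
    next_id: "itertools.count",
    video_id: str = "video",
) -> tuple[list[Track], list[Detection]]:
    """Advance the tracker by one frame.

    Predict all alive tracks, associate predictions to detection centroids by
    the Hungarian algorithm on Euclidean distance (pairs beyond
    ``gate_distance`` are discarded), update matched tracks, coast unmatched
    tracks up to ``coast_limit`` frames (emitting a synthetic box of the last
    known size at the predicted centroid), kill tracks past the limit, and
    start a new track for every unmatched detection.
    """
    predicted = [kalman_predict(t, config) for t in tracks if t.alive]
    det_centroids = [centroid(d) for d in frame_detections]

    matches: dict[int, int] = {}  # track idx -> det idx
    if predicted and det_centroids:
        cost = np.array(
            [
                [
                    float(np.hypot(p[0] - c[0], p[1] - c[1]))
                    for c in det_centroids
                ]
                for p in (t.position for t in predicted)
            ]
        )
        for ti, di in hungarian_assign(cost):
            if cost[ti, di] <= config.gate_distance:
                matches[ti] = di

    out_tracks: list[Track] = []
    out_dets: list[Detection] = []

    for ti, track in enumerate(predicted):
        if ti in matches:
            det = frame_detections[matches[ti]]
            updated = kalman_update(track, det_centroids[matches[ti]], config)
            updated = replace(
                updated,
                last_box_size=(det.box.width, det.box.height),
                last_score=det.score,
                frames_since_detection=0,
            )
            out_tracks.append(updated)
            out_dets.append(det.with_track(track.track_id))
        else:
            misses = track.frames_since_detection + 1
            if misses <= config.coast_limit:
                coasting = replace(track, frames_since_detection=misses)
                out_tracks.append(coasting)
                out_dets.append(_coasted_detection(coasting, frame_index, video_id))
            # past the limit: track dies silently, nothing emitted

    matched_dets = set(matches.values())
    for di, det in enumerate(frame_detections):
        if di not in matched_dets:
            track = new_track(next(next_id), det, config)
            out_tracks.append(track)
            out_dets.append(det.with_track(track.track_id))

    return out_tracks, out_dets


def run_tracker(
    detections: Iterable[Detection] | dict[int, list[Detection]],
    config: TrackerConfig = TrackerConfig(),
    frame_range: tuple[int, int] | None = None,
) -> list[Detection]:
    """Track a whole detection stream; returns the stream with track ids plus
    coasted fill-ins, frame-ordered.

    Frames are processed consecutively from the first to the last detection
    frame (or over ``frame_range``), so gaps with no detections still advance
    the filters and produce coasted boxes.  For every output frame there is
    at most one detection per track id.
    """
    if isinstance(detections, dict):
        by_frame = {k: list(v) for k, v in detections.items()}
    else:
        by_frame = {}
        for det in detections:
            by_frame.setdefault(det.frame_index, []).append(det)
    if not by_frame and frame_range is None:
        return []

    if frame_range is not None:
        first, last = frame_range
    else:
        first, last = min(by_frame), max(by_frame)
    video_id = next(
        (d.video_id for dets in by_frame.values() for d in dets), "video"
    )

    tracks: list[Track] = []
    next_id = itertools.count(1)
    out: list[Detection] = []
    for frame_index in range(first, last + 1):
        tracks, dets = tracker_step(
            tracks,
            by_frame.get(frame_index, []),
            config,
            frame_index,
            next_id,
            video_id,
        )
        out.extend(dets)
    return out
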
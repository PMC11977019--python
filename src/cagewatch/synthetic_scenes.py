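"""Seeded generator of home-cage-like video with exact ground truth.

Real home-cage footage of macaques is rarely shareable, so every algorithm in
this package is exercised on synthetic scenes that emulate the challenges
such footage presents: single or paired moving subjects, occlusion by railing
bars and enrichment objects, glass reflections, overexposure episodes, sensor
noise, and animals visible in a neighbouring (non-focal, ignored) cage.

Subjects are textured deformable blobs — two overlapping ellipses whose
eccentricity pulses over time, carrying a filtered-noise fur texture — not
photorealistic animals: the detectors under test respond to contrast and
motion only, and fixtures must be small and fast.  Subjects follow waypoint
paths at constant speed, with optional stationary episodes during which both
position and body deformation freeze (a resting animal is still).

Geometry is computed on the integer pixel grid and all randomness comes from
``numpy.random.default_rng(seed)``, so identical config + seed reproduces
byte-identical frames and ground truth on any platform.

Default scene resolution for fixtures is 320x180 — a scale-preserving
quarter of the 1280x720 cage-camera format — with 15 frames per second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .io_formats import (
    BoundingBox,
    Detection,
    GroundTruthInstance,
    ValidationError,
)

__all__ = [
    "SubjectConfig",
    "SceneConfig",
    "SceneBundle",
    "render_scene",
    "iter_scene_frames",
    "scene_ground_truth",
    "perfect_detections",
    "corrupt_detections",
    "delete_detection_gap",
    "standard_fixture_suite",
    "write_via_ground_truth",
]


@dataclass(frozen=True)
class SubjectConfig:
    """One animal: elliptical body, waypoint path, optional rest episodes."""

    instance_id: str
    waypoints: tuple[tuple[float, float], ...]  # visited at constant speed
    speed: float = 2.0  # px/frame along the path
    semi_axes: tuple[float, float] = (22.0, 14.0)  # body ellipse (a, b), px
    head_axes: tuple[float, float] = (13.0, 10.0)  # second ellipse
    head_offset: tuple[float, float] = (11.0, -4.0)  # relative to body centre
    pulse_amplitude: float = 0.08  # fractional axis modulation
    pulse_period: float = 45.0  # frames
    stationary: tuple[tuple[int, int], ...] = ()  # [start, end) rest episodes
    base_color: tuple[int, int, int] = (105, 72, 48)  # fur RGB
    texture_contrast: float = 22.0
    ignore: bool = False  # True for neighbouring-cage animals


@dataclass(frozen=True)
class SceneConfig:
    """Full scene description; identical config + seed gives identical output."""

    video_id: str = "scene"
    frame_size: tuple[int, int] = (320, 180)  # (width, height)
    fps: float = 15.0
    n_frames: int = 300
    subjects: tuple[SubjectConfig, ...] = ()
    railing_period: int = 0  # 0 disables the vertical-bar occluder
    railing_width: int = 3
    enrichment: tuple[tuple[float, float, float, float], ...] = ()  # opaque boxes
    overexposure: tuple[tuple[int, int, float], ...] = ()  # (start, end, +delta)
    reflection: tuple[tuple[float, float, float, float], float] | None = None
    ignore_region: tuple[float, float, float, float] | None = None
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.frame_size
        for s in self.subjects:
            if 2 * s.semi_axes[0] >= w or 2 * s.semi_axes[1] >= h:
                raise ValidationError(
                    f"subject {s.instance_id!r} larger than the frame"
                )


# ---------------------------------------------------------------------------
# subject geometry
# ---------------------------------------------------------------------------


def _path_position(subject: SubjectConfig, distance: float) -> tuple[float, float]:
    pts = subject.waypoints
    if len(pts) == 1:
        return pts[0]
    remaining = distance
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        if remaining <= seg or seg == 0:
            t = 0.0 if seg == 0 else remaining / seg
            return (x0 + t * (x1 - x0), y0 + t * (y1 - y0))
        remaining -= seg
    return pts[-1]


def _effective_time(subject: SubjectConfig, frame_idx: int) -> float:
    """Frames of actual motion up to ``frame_idx``: rest episodes freeze the
    clock, so both position and deformation phase hold."""
    t = 0.0
    for f in range(frame_idx):
        in_rest = any(a <= f < b for a, b in subject.stationary)
        if not in_rest:
            t += 1.0
    return t


def _subject_state(
    subject: SubjectConfig, frame_idx: int
) -> tuple[tuple[float, float], float]:
    t = _effective_time(subject, frame_idx)
    center = _path_position(subject, subject.speed * t)
    phase = 2.0 * math.pi * t / subject.pulse_period
    return center, phase


def _subject_mask(
    shape: tuple[int, int], subject: SubjectConfig, frame_idx: int
) -> np.ndarray:
    """Boolean pixel mask of the deformable two-ellipse body."""
    (cx, cy), phase = _subject_state(subject, frame_idx)
    pulse = subject.pulse_amplitude * math.sin(phase)
    a = subject.semi_axes[0] * (1.0 + pulse)
    b = subject.semi_axes[1] * (1.0 - pulse)
    a2 = subject.head_axes[0] * (1.0 + 0.5 * pulse)
    b2 = subject.head_axes[1]
    ox, oy = subject.head_offset

    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    body = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    head = ((xs - (cx + ox)) / a2) ** 2 + ((ys - (cy + oy)) / b2) ** 2 <= 1.0
    return body | head


def _mask_box(mask: np.ndarray) -> BoundingBox | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    return BoundingBox(
        float(cols.min()), float(rows.min()), float(cols.max() + 1), float(rows.max() + 1)
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_TEX = 256  # fur/background texture tile size


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, ...], passes: int = 3) -> np.ndarray:
    """Low-pass filtered noise in [-1, 1] via repeated box blur of white noise."""
    field_ = rng.standard_normal(shape)
    for _ in range(passes):
        acc = field_.copy()
        for axis in (0, 1):
            acc += np.roll(field_, 1, axis=axis) + np.roll(field_, -1, axis=axis)
        field_ = acc / 5.0
    peak = np.abs(field_).max()
    return field_ / peak if peak > 0 else field_


def _static_layers(config: SceneConfig, rng: np.random.Generator):
    """Background image, per-subject fur texture tiles, occluder overlay."""
    w, h = config.frame_size
    ys = np.linspace(0.0, 1.0, h)[:, None]
    xs = np.linspace(0.0, 1.0, w)[None, :]
    base = np.empty((h, w, 3), np.float32)
    base[..., 0] = 110 + 12 * xs + 6 * ys
    base[..., 1] = 115 + 8 * xs - 4 * ys
    base[..., 2] = 125 - 6 * xs + 10 * ys
    base += 5.0 * _smooth_noise(rng, (h, w))[..., None]

    textures = {
        s.instance_id: (
            np.asarray(s.base_color, np.float32)
            + s.texture_contrast * _smooth_noise(rng, (_TEX, _TEX))[..., None]
        )
        for s in config.subjects
    }

    occluder = np.full((h, w), False)
    occluder_color = np.zeros((h, w, 3), np.float32)
    if config.railing_period > 0:
        bar_cols = (np.arange(w) % config.railing_period) < config.railing_width
        occluder[:, bar_cols] = True
        occluder_color[:, bar_cols] = (58.0, 60.0, 64.0)
    for x0, y0, x1, y1 in config.enrichment:
        r0, r1 = int(round(y0)), int(round(y1))
        c0, c1 = int(round(x0)), int(round(x1))
        occluder[r0:r1, c0:c1] = True
        occluder_color[r0:r1, c0:c1] = (150.0, 120.0, 70.0)

    reflection_pattern = None
    if config.reflection is not None:
        reflection_pattern = 200.0 + 40.0 * _smooth_noise(rng, (h, w))
    return base, textures, occluder, occluder_color, reflection_pattern


def _render_frame(
    config: SceneConfig,
    frame_idx: int,
    layers,
    rng: np.random.Generator,
) -> np.ndarray:
    base, textures, occluder, occluder_color, reflection = layers
    h, w = base.shape[:2]
    frame = base.copy()

    for subject in config.subjects:
        mask = _subject_mask((h, w), subject, frame_idx)
        if not mask.any():
            continue
        (cx, cy), _ = _subject_state(subject, frame_idx)
        rows, cols = np.nonzero(mask)
        # fur texture anchored to the body so it translates with the subject
        tr = np.mod(rows - int(round(cy)), _TEX)
        tc = np.mod(cols - int(round(cx)), _TEX)
        frame[rows, cols] = textures[subject.instance_id][tr, tc]

    frame = np.where(occluder[..., None], occluder_color, frame)

    if config.reflection is not None:
        (x0, y0, x1, y1), alpha = config.reflection
        r0, r1 = int(round(y0)), int(round(y1))
        c0, c1 = int(round(x0)), int(round(x1))
        frame[r0:r1, c0:c1] = (
            (1 - alpha) * frame[r0:r1, c0:c1] + alpha * reflection[r0:r1, c0:c1, None]
        )

    for start, end, delta in config.overexposure:
        if start <= frame_idx < end:
            frame = frame + delta

    if config.noise_std > 0:
        frame = frame + rng.normal(0.0, config.noise_std, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def scene_ground_truth(config: SceneConfig) -> dict[int, list[GroundTruthInstance]]:
    """Exact annotations: per subject per frame, the tight pixel bounds of the
    rendered body *before* occluder overdraw (an occluded animal's box still
    covers all body parts); neighbouring-cage subjects carry ignore=True."""
    w, h = config.frame_size
    gt: dict[int, list[GroundTruthInstance]] = {}
    for frame_idx in range(config.n_frames):
        instances = []
        for subject in config.subjects:
            box = _mask_box(_subject_mask((h, w), subject, frame_idx))
            if box is not None:
                instances.append(
                    GroundTruthInstance(
                        frame_index=frame_idx,
                        instance_id=subject.instance_id,
                        box=box,
                        ignore=subject.ignore,
                    )
                )
        gt[frame_idx] = instances
    return gt


def iter_scene_frames(config: SceneConfig) -> Iterator[np.ndarray]:
    """Render frames one at a time (uint8 RGB)."""
    rng = np.random.default_rng(config.seed)
    layers = _static_layers(config, rng)
    for frame_idx in range(config.n_frames):
        yield _render_frame(config, frame_idx, layers, rng)


def render_scene(
    config: SceneConfig,
) -> tuple[list[np.ndarray], dict[int, list[GroundTruthInstance]]]:
    """Render the whole scene into memory; returns (frames, ground truth)."""
    return list(iter_scene_frames(config)), scene_ground_truth(config)


def scene_frame_refs(config: SceneConfig):
    """Frames wrapped as FrameRef, lazily."""
    from .io_formats import FrameRef

    for idx, image in enumerate(iter_scene_frames(config)):
        yield FrameRef(video_id=config.video_id, frame_index=idx, image=image)


# ---------------------------------------------------------------------------
# detection-stream corruption
# ---------------------------------------------------------------------------


def perfect_detections(
    gt: Mapping[int, Sequence[GroundTruthInstance]], video_id: str = "scene"
) -> dict[int, list[Detection]]:
    """Ideal detector output: every non-ignored annotation, score 1."""
    out: dict[int, list[Detection]] = {}
    for frame_idx, instances in gt.items():
        out[frame_idx] = [
            Detection(
                frame_index=frame_idx, box=g.box, score=1.0, video_id=video_id
            )
            for g in instances
            if not g.ignore
        ]
    return out


def corrupt_detections(
    gt: Mapping[int, Sequence[GroundTruthInstance]],
    dropout_rate: float = 0.0,
    fp_rate: float = 0.0,
    jitter_px: float = 0.0,
    seed: int = 0,
    frame_size: tuple[int, int] = (320, 180),
    video_id: str = "scene",
    tp_score_range: tuple[float, float] = (0.75, 1.0),
    fp_score_range: tuple[float, float] = (0.50, 0.70),
) -> dict[int, list[Detection]]:
    """Degrade ground truth into a realistic detection stream.

    Each non-ignored box is independently dropped with ``dropout_rate``;
    survivors are shifted by a uniform +-``jitter_px`` offset and scored from
    the high (true-positive) range.  False positives are injected per frame
    with probability ``fp_rate`` at random positions, scored from the low
    range — so a confidence threshold at the range boundary separates them.
    """
    if not (0.0 <= dropout_rate < 1.0 and 0.0 <= fp_rate < 1.0):
        raise ValidationError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    w, h = frame_size
    out: dict[int, list[Detection]] = {}
    for frame_idx in sorted(gt):
        dets: list[Detection] = []
        for g in gt[frame_idx]:
            if g.ignore or rng.random() < dropout_rate:
                continue
            dx = rng.uniform(-jitter_px, jitter_px) if jitter_px > 0 else 0.0
            dy = rng.uniform(-jitter_px, jitter_px) if jitter_px > 0 else 0.0
            box = BoundingBox(
                g.box.x_min + dx, g.box.y_min + dy, g.box.x_max + dx, g.box.y_max + dy
            )
            dets.append(
                Detection(
                    frame_index=frame_idx,
                    box=box,
                    score=float(rng.uniform(*tp_score_range)),
                    video_id=video_id,
                )
            )
        if rng.random() < fp_rate:
            bw, bh = rng.uniform(10, 30), rng.uniform(8, 20)
            x0 = rng.uniform(0, w - bw)
            y0 = rng.uniform(0, h - bh)
            dets.append(
                Detection(
                    frame_index=frame_idx,
                    box=BoundingBox(x0, y0, x0 + bw, y0 + bh),
                    score=float(rng.uniform(*fp_score_range)),
                    video_id=video_id,
                )
            )
        out[frame_idx] = dets
    return out


def delete_detection_gap(
    dets: Mapping[int, Sequence[Detection]], start: int, length: int
) -> dict[int, list[Detection]]:
    """Remove all detections on frames [start, start+length) — the missed-
    detection episode the tracker is expected to bridge."""
    return {
        fi: ([] if start <= fi < start + length else list(frame_dets))
        for fi, frame_dets in dets.items()
    }


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneBundle:
    """One named fixture: scene config, ground truth, a detection stream, and
    lazily rendered frames (videos are large; render on demand)."""

    name: str
    config: SceneConfig
    gt: dict[int, list[GroundTruthInstance]]
    detections: dict[int, list[Detection]]
    notes: str = ""

    def iter_frames(self) -> Iterator[np.ndarray]:
        return iter_scene_frames(self.config)

    def frame_refs(self):
        return scene_frame_refs(self.config)


def _walk_subject(video_id: str, frame_size, speed=2.0, **kw) -> SubjectConfig:
    w, h = frame_size
    m = 40  # margin keeps the body inside the frame
    return SubjectConfig(
        instance_id="macaque_A",
        waypoints=((m, h / 2), (w - m, h / 2 - 20), (m + 20, h - m), (w - m, m + 10)),
        speed=speed,
        **kw,
    )


def standard_fixture_suite(
    frame_size: tuple[int, int] = (320, 180), n_frames: int = 300
) -> dict[str, SceneBundle]:
    """The canonical seeded fixtures every behavioural test runs on.

    ``single_clean``          one moving textured subject, no occluders
    ``single_static_subject`` the same subject resting for the whole video
    ``single_overexposed``    moving subject plus global +60 brightness episodes
    ``paired_overlap``        two subjects on crossing paths (overlap episode)
    ``neighbour_ignore``      moving subject plus an ignored neighbouring animal
    ``dropout_gap5``          clean stream with detections deleted on 5 frames
    ``dropout_gap25``         same with a 25-frame gap (exceeds the coast limit)
    """
    w, h = frame_size
    suite: dict[str, SceneBundle] = {}

    def bundle(name, config, detections=None, notes=""):
        gt = scene_ground_truth(config)
        dets = detections if detections is not None else perfect_detections(gt, name)
        suite[name] = SceneBundle(name, config, gt, dets, notes)

    clean_cfg = SceneConfig(
        video_id="single_clean",
        frame_size=frame_size,
        n_frames=n_frames,
        subjects=(_walk_subject("single_clean", frame_size),),
        seed=101,
    )
    bundle("single_clean", clean_cfg, notes="moving subject, no occluders")

    static_cfg = replace(
        clean_cfg,
        video_id="single_static_subject",
        subjects=(
            replace(
                _walk_subject("single_static_subject", frame_size),
                stationary=((0, n_frames),),
            ),
        ),
        seed=102,
    )
    bundle(
        "single_static_subject",
        static_cfg,
        notes="resting subject is absorbed into the synthesized background",
    )

    over_cfg = replace(
        clean_cfg,
        video_id="single_overexposed",
        overexposure=((n_frames // 3, n_frames // 3 + 40, 60.0),),
        seed=103,
    )
    bundle("single_overexposed", over_cfg, notes="+60 global brightness episode")

    m = 40
    paired_cfg = SceneConfig(
        video_id="paired_overlap",
        frame_size=frame_size,
        n_frames=n_frames,
        subjects=(
            SubjectConfig(
                instance_id="macaque_A",
                waypoints=((m, m), (w - m, h - m), (m, h - m)),
                speed=2.0,
            ),
            SubjectConfig(
                instance_id="macaque_B",
                waypoints=((w - m, m), (m, h - m), (w - m, h - m)),
                speed=2.0,
                base_color=(90, 85, 60),
            ),
        ),
        seed=104,
    )
    bundle("paired_overlap", paired_cfg, notes="crossing paths, overlap episode")

    neigh_region = (float(w - 80), 0.0, float(w), 42.0)
    neigh_cfg = replace(
        clean_cfg,
        video_id="neighbour_ignore",
        subjects=clean_cfg.subjects
        + (
            SubjectConfig(
                instance_id="neighbour",
                waypoints=((w - 65, 20), (w - 18, 20)),
                speed=0.5,
                semi_axes=(11.0, 8.0),
                head_axes=(6.0, 5.0),
                head_offset=(6.0, -2.0),
                base_color=(95, 80, 60),
                ignore=True,
            ),
        ),
        ignore_region=neigh_region,
        seed=105,
    )
    bundle("neighbour_ignore", neigh_cfg, notes="ignored neighbouring-cage animal")

    # tracking fixtures: rigid body (no pulse) so the box centroid moves linearly
    line_cfg = SceneConfig(
        video_id="dropout_gap5",
        frame_size=frame_size,
        n_frames=min(n_frames, 150),
        subjects=(
            SubjectConfig(
                instance_id="macaque_A",
                waypoints=((m, h / 2), (w - m, h / 2)),
                speed=1.5,
                pulse_amplitude=0.0,
            ),
        ),
        seed=106,
    )
    gap5_gt = scene_ground_truth(line_cfg)
    suite["dropout_gap5"] = SceneBundle(
        "dropout_gap5",
        line_cfg,
        gap5_gt,
        delete_detection_gap(perfect_detections(gap5_gt, "dropout_gap5"), 50, 5),
        notes="5-frame missed-detection gap; the tracker should bridge it",
    )

    gap25_cfg = replace(line_cfg, video_id="dropout_gap25", seed=107)
    gap25_gt = scene_ground_truth(gap25_cfg)
    suite["dropout_gap25"] = SceneBundle(
        "dropout_gap25",
        gap25_cfg,
        gap25_gt,
        delete_detection_gap(perfect_detections(gap25_gt, "dropout_gap25"), 50, 25),
        notes="25-frame gap exceeds the 20-frame coast limit: track dies",
    )
    return suite


# ---------------------------------------------------------------------------
# VIA-compatible ground-truth export
# ---------------------------------------------------------------------------


def write_via_ground_truth(
    gt: Mapping[int, Sequence[GroundTruthInstance]], path, video_id: str = "scene"
) -> None:
    """Write annotations as a VIA 2.x-compatible project (rect regions with
    ``id`` and ``ignore`` attributes) so the reader path is exercised on
    synthetic data too."""
    metadata = {}
    for frame_idx in sorted(gt):
        filename = f"{video_id}_{frame_idx:06d}.png"
        regions = []
        for g in gt[frame_idx]:
            regions.append(
                {
                    "shape_attributes": {
                        "name": "rect",
                        "x": g.box.x_min,
                        "y": g.box.y_min,
                        "width": g.box.width,
                        "height": g.box.height,
                    },
                    "region_attributes": {
                        "id": g.instance_id,
                        "ignore": "1" if g.ignore else "0",
                    },
                }
            )
        metadata[filename] = {"filename": filename, "size": -1, "regions": regions}
    with open(path, "w") as fh:
        json.dump({"_via_img_metadata": metadata}, fh)
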
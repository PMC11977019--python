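"""External representations: video frames, VIA annotation projects, the
detections interchange CSV, and evaluation reports.

Coordinate convention
---------------------
All boxes are 0-based, half-open ``[x_min, x_max) x [y_min, y_max)`` so that a
box drawn around an ``h x w`` pixel block has area ``h * w`` and maps directly
onto array slices.  A VIA rectangle ``(x, y, width, height)`` therefore becomes
``(x, y, x + width, y + height)``.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input value violates a documented invariant."""


class ParseError(ValueError):
    """Raised when an external file cannot be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based half-open coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}): min must be < max"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @staticmethod
    def from_polygon(points: Sequence[tuple[float, float]]) -> "BoundingBox":
        """Tight axis-aligned bounds of a polygon's vertices."""
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        return BoundingBox(min(xs), min(ys), max(xs), max(ys))


@dataclass(frozen=True)
class FrameRef:
    """One decoded video frame with its original index in the stream."""

    video_id: str
    frame_index: int
    image: np.ndarray  # H x W x 3 uint8, RGB

    def __post_init__(self) -> None:
        img = self.image
        if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
            raise ValidationError(
                f"frame {self.frame_index}: expected HxWx3 uint8, got "
                f"shape {img.shape} dtype {img.dtype}"
            )
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")


@dataclass(frozen=True)
class GroundTruthInstance:
    """An annotated animal: tight box, optional polygon outline, identity,
    and an ignore flag for animals in neighbouring (non-focal) cages.

    Ignored instances never contribute true positives or false negatives;
    detections overlapping them are discarded from scoring.
    """

    frame_index: int
    instance_id: str
    box: BoundingBox
    polygon: tuple[tuple[float, float], ...] | None = None
    ignore: bool = False

    def __post_init__(self) -> None:
        if self.polygon is not None:
            if len(self.polygon) < 3:
                raise ValidationError(
                    f"frame {self.frame_index} instance {self.instance_id!r}: "
                    f"polygon needs >= 3 vertices, got {len(self.polygon)}"
                )
            tight = BoundingBox.from_polygon(self.polygon)
            if any(
                not math.isclose(a, b, abs_tol=1e-9)
                for a, b in zip(tight.as_tuple(), self.box.as_tuple())
            ):
                raise ValidationError(
                    f"frame {self.frame_index} instance {self.instance_id!r}: "
                    "box does not equal the polygon's tight bounds"
                )


@dataclass(frozen=True)
class Detection:
    """A scored detector output box, optionally carrying a binary mask and,
    after tracking, a track id.  ``coasted`` marks boxes synthesized by the
    tracker while a target went undetected."""

    frame_index: int
    box: BoundingBox
    score: float
    mask: np.ndarray | None = None  # H x W bool, tight bounds == box
    track_id: int | None = None
    coasted: bool = False
    video_id: str = "video"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")

    def with_track(self, track_id: int, coasted: bool = False) -> "Detection":
        return replace(self, track_id=track_id, coasted=coasted)


# ---------------------------------------------------------------------------
# VIA project reading
# ---------------------------------------------------------------------------

_TRUE_VALUES = {"1", "true", "yes"}


def _frame_index_from_filename(filename: str, fallback: int) -> int:
    """VIA keys images by filename; pull a trailing integer if present."""
    stem = Path(filename).stem
    digits = ""
    for ch in reversed(stem):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    return int(digits) if digits else fallback


def read_via_project(path: str | os.PathLike) -> dict[int, list[GroundTruthInstance]]:
    """Read a VIA 2.x project JSON into ground-truth instances grouped by frame.

    Regions of shape ``polygon`` yield instances carrying both the polygon and
    its tight bounding box; ``rect`` regions yield box-only instances.  A
    region attribute ``ignore`` with value ``1``/``true`` (case-insensitive)
    sets the ignore flag; a region attribute ``id`` sets the instance id
    (sequential within the frame otherwise).
    """
    with open(path) as fh:
        try:
            project = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc

    # Either a bare img_metadata mapping or a full project with _via_img_metadata.
    metadata = project.get("_via_img_metadata", project)
    if not isinstance(metadata, dict):
        raise ParseError(f"{path}: missing key '_via_img_metadata'")

    out: dict[int, list[GroundTruthInstance]] = {}
    for fallback_idx, (img_key, entry) in enumerate(sorted(metadata.items())):
        if not isinstance(entry, dict) or "regions" not in entry:
            raise ParseError(f"{path}: image entry {img_key!r} missing key 'regions'")
        frame_index = _frame_index_from_filename(
            entry.get("filename", img_key), fallback_idx
        )
        instances: list[GroundTruthInstance] = []
        for region_idx, region in enumerate(entry["regions"]):
            try:
                shape = region["shape_attributes"]
                shape_name = shape["name"]
            except (KeyError, TypeError) as exc:
                raise ParseError(
                    f"{path}: image {img_key!r} region {region_idx} missing key "
                    f"'shape_attributes'/'name'"
                ) from exc
            attrs = region.get("region_attributes", {})
            ignore = str(attrs.get("ignore", "")).strip().lower() in _TRUE_VALUES
            instance_id = str(attrs.get("id", "")) or f"instance_{region_idx}"

            if shape_name == "rect":
                try:
                    x, y = shape["x"], shape["y"]
                    w, h = shape["width"], shape["height"]
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: image {img_key!r} region {region_idx} rect "
                        f"missing key {exc}"
                    ) from exc
                box = BoundingBox(x, y, x + w, y + h)
                polygon = None
            elif shape_name == "polygon":
                try:
                    xs = shape["all_points_x"]
                    ys = shape["all_points_y"]
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: image {img_key!r} region {region_idx} polygon "
                        f"missing key {exc}"
                    ) from exc
                if len(xs) != len(ys):
                    raise ParseError(
                        f"{path}: image {img_key!r} region {region_idx}: "
                        "all_points_x/all_points_y length mismatch"
                    )
                if len(xs) < 3:
                    raise ValidationError(
                        f"image {img_key!r} region {region_idx}: polygon with "
                        f"{len(xs)} < 3 vertices"
                    )
                polygon = tuple(zip(map(float, xs), map(float, ys)))
                box = BoundingBox.from_polygon(polygon)
            else:
                raise ParseError(
                    f"{path}: image {img_key!r} region {region_idx}: unsupported "
                    f"shape {shape_name!r} (expected 'rect' or 'polygon')"
                )
            instances.append(
                GroundTruthInstance(
                    frame_index=frame_index,
                    instance_id=instance_id,
                    box=box,
                    polygon=polygon,
                    ignore=ignore,
                )
            )
        out.setdefault(frame_index, []).extend(instances)
    return out


# ---------------------------------------------------------------------------
# detections interchange CSV
# ---------------------------------------------------------------------------

_DET_FIELDS = [
    "video_id",
    "frame_index",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "score",
    "track_id",
    "coasted",
]


def write_detections(
    detections: Iterable[Detection], path: str | os.PathLike
) -> None:
    """Write detections to the interchange CSV, one row per box.

    Floats are written with 6 decimals; ``track_id`` is blank when unset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DET_FIELDS)
        for det in detections:
            writer.writerow(
                [
                    det.video_id,
                    det.frame_index,
                    f"{det.box.x_min:.6f}",
                    f"{det.box.y_min:.6f}",
                    f"{det.box.x_max:.6f}",
                    f"{det.box.y_max:.6f}",
                    f"{det.score:.6f}",
                    "" if det.track_id is None else det.track_id,
                    int(det.coasted),
                ]
            )


def read_detections(path: str | os.PathLike) -> dict[int, list[Detection]]:
    """Read the interchange CSV back into detections grouped by frame index."""
    out: dict[int, list[Detection]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header row required") from None
        required = _DET_FIELDS[:7]
        if header[: len(required)] != required:
            raise ParseError(
                f"{path}: bad header {header[:len(required)]}, expected {required}"
            )
        has_track = "track_id" in header
        has_coasted = "coasted" in header
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                video_id = row[0]
                frame_index = int(row[1])
                coords = tuple(float(v) for v in row[2:6])
                score = float(row[6])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: row {row_no}: {exc}") from exc
            track_id: int | None = None
            coasted = False
            if has_track and len(row) > 7 and row[7] != "":
                track_id = int(row[7])
            if has_coasted and len(row) > 8 and row[8] != "":
                coasted = bool(int(row[8]))
            try:
                det = Detection(
                    frame_index=frame_index,
                    box=BoundingBox(*coords),
                    score=score,
                    track_id=track_id,
                    coasted=coasted,
                    video_id=video_id,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
            out.setdefault(frame_index, []).append(det)
    return out


def flatten_detections(by_frame: dict[int, list[Detection]]) -> list[Detection]:
    """Frame-grouped detections as a single frame-ordered list."""
    out: list[Detection] = []
    for frame_index in sorted(by_frame):
        out.extend(by_frame[frame_index])
    return out


# ---------------------------------------------------------------------------
# video frame reading
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def _to_rgb_uint8(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def _iter_raw_frames(path: Path) -> Iterator[np.ndarray]:
    import imageio.v3 as iio

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise IOError(f"{path}: directory contains no image frames")
        for p in files:
            yield iio.imread(p)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            for page in tif.pages:
                yield page.asarray()
    else:
        yield from iio.imiter(path)


def read_video_frames(
    path: str | os.PathLike, stride: int = 1, video_id: str | None = None
) -> Iterator[FrameRef]:
    """Yield every ``stride``-th frame of a video as :class:`FrameRef`.

    ``frame_index`` keeps the original position in the stream (0, stride,
    2*stride, ...), not the subsampled position.  Supported containers:
    multi-page TIFF stacks, directories of ordered image files, and any
    format the imageio backend can iterate.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file or directory")
    vid = video_id if video_id is not None else path.stem
    for idx, frame in enumerate(_iter_raw_frames(path)):
        if idx % stride == 0:
            yield FrameRef(video_id=vid, frame_index=idx, image=_to_rgb_uint8(frame))


def write_video_frames(
    frames: Iterable[np.ndarray], path: str | os.PathLike
) -> None:
    """Write a frame sequence as a multi-page TIFF stack (the round-trippable
    container used for synthetic footage)."""
    import tifffile

    tifffile.imwrite(path, np.stack([np.asarray(f) for f in frames]))
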
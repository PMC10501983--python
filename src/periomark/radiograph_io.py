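"""Image, detection, annotation and report I/O.

Coordinate conventions (used throughout the package):

* origin at the upper-left corner, ``y`` grows downward;
* pixel indices are 0-based;
* a bounding box occupies the half-open region ``[x, x+w) x [y, y+h)``.

A :class:`Radiograph` carries the intensity grid (float array in
[0, 255]) plus the vertical calibration in mm per pixel (default 0.063,
established for the nominal 410x340 acquisition geometry).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import FormatError, ImageIOError, ParameterError

DEFAULT_MM_PER_PX = 0.063
STANDARD_SIZE = (410, 340)  # (width, height)

CROWN = "crown"
SCREW = "screw"

UPPER = "upper"
LOWER = "lower"
UNKNOWN = "unknown"


@dataclass
class Radiograph:
    """8-bit grayscale intraoral radiograph with vertical calibration."""

    pixels: np.ndarray                      # (height, width) float64 in [0,255]
    mm_per_px_vertical: float = DEFAULT_MM_PER_PX
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("pixels must be a non-empty 2D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ParameterError("intensities must lie in [0, 255]")
        if self.mm_per_px_vertical <= 0:
            raise ParameterError("mm_per_px_vertical must be > 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BoundingBox:
    """Detector box: upper-left corner (x, y), width w, height h, score."""

    label: str
    x: float
    y: float
    w: float
    h: float
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in (CROWN, SCREW):
            raise FormatError(f"unknown label {self.label!r}")
        if self.w <= 0 or self.h <= 0:
            raise FormatError("box width and height must be > 0")
        if not 0.0 <= self.score <= 1.0:
            raise FormatError("score must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def clamped(self, width: int, height: int) -> "BoundingBox":
        """Intersect the box with the image frame."""
        x0 = max(self.x, 0.0)
        y0 = max(self.y, 0.0)
        x1 = min(self.x + self.w, float(width))
        y1 = min(self.y + self.h, float(height))
        if x1 <= x0 or y1 <= y0:
            raise FormatError("box does not intersect the image")
        return dataclasses.replace(self, x=x0, y=y0, w=x1 - x0, h=y1 - y0)

    def scaled(self, fx: float, fy: float) -> "BoundingBox":
        return dataclasses.replace(
            self, x=self.x * fx, y=self.y * fy, w=self.w * fx, h=self.h * fy
        )


@dataclass
class DetectionSet:
    """Crown/screw boxes of one image plus the jaw-side classification."""

    boxes: list[BoundingBox] = field(default_factory=list)
    jaw: str = UNKNOWN

    def by_label(self, label: str) -> list[BoundingBox]:
        return [b for b in self.boxes if b.label == label]


@dataclass
class AnnotatedEdge:
    """Ground truth for one screw edge: control points (>= 10), the two
    critical points, and the reference resorption percentage."""

    points: np.ndarray                       # (n, 2) array of (x, y)
    critical: list[tuple[float, float]] = field(default_factory=list)
    resorption_pct: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise FormatError("edge points must be an (n, 2) array")
        if len(self.points) < 10:
            raise FormatError("each annotated edge needs >= 10 points")
        if self.resorption_pct is not None and not 0 <= self.resorption_pct <= 100:
            raise FormatError("resorption_pct must lie in [0, 100]")


@dataclass
class AnnotationSet:
    edges: list[AnnotatedEdge] = field(default_factory=list)
    jaw: str = UNKNOWN


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    mm_per_px_vertical: float = DEFAULT_MM_PER_PX,
) -> Radiograph:
    """Read a JPEG/PNG radiograph as grayscale.

    Color inputs are collapsed with an unweighted channel mean:
    radiographs are effectively monochrome, so no luma weighting.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img, dtype=float)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageIOError(f"image {path} is empty")
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return Radiograph(
        np.clip(arr, 0, 255), mm_per_px_vertical=mm_per_px_vertical,
        source_id=path.stem,
    )


def write_image(r: Radiograph, path: str | Path) -> None:
    arr = np.clip(np.rint(r.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def resize_to_standard(
    r: Radiograph,
    target_w: int = STANDARD_SIZE[0],
    target_h: int = STANDARD_SIZE[1],
    detections: DetectionSet | None = None,
):
    """Bicubic resize to the working resolution (nominally 410x340).

    When a :class:`DetectionSet` is supplied its boxes are scaled by the
    same factors and the pair ``(radiograph, detections)`` is returned.
    """
    if target_w < 1 or target_h < 1:
        raise ParameterError("target dimensions must be >= 1")
    fx = target_w / r.width
    fy = target_h / r.height
    if (target_h, target_w) == r.pixels.shape:
        out = Radiograph(r.pixels.copy(), r.mm_per_px_vertical, r.source_id)
    else:
        resized = _sk_resize(
            r.pixels, (target_h, target_w), order=3,
            anti_aliasing=(fx < 1 or fy < 1), preserve_range=True,
        )
        out = Radiograph(
            np.clip(resized, 0, 255), r.mm_per_px_vertical, r.source_id
        )
    if detections is None:
        return out
    scaled = DetectionSet(
        boxes=[b.scaled(fx, fy) for b in detections.boxes], jaw=detections.jaw
    )
    return out, scaled


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

_YOLO_CLASSES = {0: CROWN, 1: SCREW}


def read_detections(
    path: str | Path,
    format: str | None = None,
    image_size: tuple[int, int] = STANDARD_SIZE,
    score_min: float = 0.5,
) -> DetectionSet:
    """Read crown/screw detections from JSON or YOLO-style text.

    Records with ``score <= score_min`` are dropped (the detector's
    objectness must be *greater than* 0.5). Boxes are clamped to the
    image frame. The jaw side is classified from the surviving boxes.
    """
    path = Path(path)
    if format is None:
        format = "yolo_txt" if path.suffix.lower() == ".txt" else "json"
    if format == "json":
        boxes = _read_detections_json(path)
    elif format == "yolo_txt":
        boxes = _read_detections_yolo(path, image_size)
    else:
        raise FormatError(f"unknown detections format {format!r}")

    width, height = image_size
    kept = [b.clamped(width, height) for b in boxes if b.score > score_min]
    dset = DetectionSet(boxes=kept)
    from .detection_gate import classify_jaw  # late import: gate uses these types

    dset.jaw = classify_jaw(dset)
    return dset


def _read_detections_json(path: Path) -> list[BoundingBox]:
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not data:
        return []
    records = data.get("boxes", []) if isinstance(data, dict) else data
    boxes = []
    for i, rec in enumerate(records):
        try:
            boxes.append(BoundingBox(
                label=rec["label"], x=float(rec["x"]), y=float(rec["y"]),
                w=float(rec["w"]), h=float(rec["h"]),
                score=float(rec.get("score", 1.0)),
            ))
        except (KeyError, TypeError, ValueError, FormatError) as exc:
            raise FormatError(f"{path}: bad record {i}: {exc}") from exc
    return boxes


def _read_detections_yolo(path: Path, image_size: tuple[int, int]) -> list[BoundingBox]:
    """Dialect: ``class cx cy w h score``, all coordinates normalized;
    class 0 = crown, 1 = screw."""
    width, height = image_size
    boxes = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h, score = map(float, parts[1:])
            label = _YOLO_CLASSES[cls]
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        boxes.append(BoundingBox(
            label=label,
            x=(cx - w / 2) * width, y=(cy - h / 2) * height,
            w=w * width, h=h * height, score=score,
        ))
    return boxes


def write_detections(dset: DetectionSet, path: str | Path, image: str = "") -> None:
    payload = {
        "image": image,
        "boxes": [
            {
                "label": b.label, "x": b.x, "y": b.y, "w": b.w, "h": b.h,
                "score": b.score,
            }
            for b in dset.boxes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationSet:
    """Annotation JSON: ``{"edges": [{"points": [[x, y], ...],
    "critical": [[x, y], [x, y]], "resorption_pct": float}], "jaw": str}``.
    Extra keys are ignored so phantom truth files (a superset) load too."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    edges = []
    for rec in data.get("edges", []):
        edges.append(AnnotatedEdge(
            points=np.asarray(rec["points"], dtype=float),
            critical=[tuple(p) for p in rec.get("critical", [])],
            resorption_pct=rec.get("resorption_pct"),
        ))
    return AnnotationSet(edges=edges, jaw=data.get("jaw", UNKNOWN))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_EDGE_CSV_FIELDS = [
    "edge_id", "implant_id", "side", "status", "percentage", "severity",
    "loss_px", "loss_mm", "y_first", "x_first", "y_second", "x_second",
]


def write_report(report, path: str | Path) -> tuple[Path, Path]:
    """Emit a resorption report as JSON (machine) plus CSV (per-edge rows).

    ``path`` may carry either suffix; both files are written next to each
    other and the (json_path, csv_path) pair is returned.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".json", ".csv"} else path
    json_path = base.with_suffix(".json")
    csv_path = base.with_suffix(".csv")
    payload = report.to_dict()
    try:
        json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_EDGE_CSV_FIELDS)
            writer.writeheader()
            for row in payload["edges"]:
                writer.writerow({k: row.get(k) for k in _EDGE_CSV_FIELDS})
    except OSError as exc:
        raise ImageIOError(f"cannot write report to {path}: {exc}") from exc
    return json_path, csv_path


def read_report(path: str | Path):
    from .resorption import ResorptionReport  # avoid import cycle

    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse report {path}: {exc}") from exc
    return ResorptionReport.from_dict(data)
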
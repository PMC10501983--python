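"""Gating before boundary analysis: jaw side, crown-screw pairing,
contrast quality.

Jaw classification uses the mean box-center y of each class: with the
origin at the top of the image, crowns sitting *above* screws
(y_c < y_s) means the implants are in the lower jaw, and vice versa.

A screw box is validated by extending it along y toward the crown side
until the far edge of a candidate crown box; the pair is accepted when
the intersection covers more than 30% of the *crown* box area.

Contrast quality is the population standard deviation of intensities
inside the union of the paired boxes, normalized by sigma_max ~ 98 (the
value observed at full contrast); 0.4 is the high/low threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import GatingError, ParameterError
from .radiograph_io import (
    CROWN, LOWER, SCREW, UNKNOWN, UPPER,
    BoundingBox, DetectionSet, Radiograph,
)


@dataclass(frozen=True)
class QualityMetric:
    sigma_raw: float
    sigma_norm: float
    high_contrast: bool


@dataclass(frozen=True)
class ImplantUnit:
    """A validated screw-crown pair."""

    screw_box: BoundingBox
    crown_box: BoundingBox
    overlap_fraction: float


def classify_jaw(d: DetectionSet) -> str:
    """Mean-y rule: lower iff y_c < y_s, upper iff y_c > y_s, unknown on
    a missing class or an exact tie."""
    crowns = d.by_label(CROWN)
    screws = d.by_label(SCREW)
    if not crowns or not screws:
        return UNKNOWN
    y_c = float(np.mean([b.center[1] for b in crowns]))
    y_s = float(np.mean([b.center[1] for b in screws]))
    if y_c < y_s:
        return LOWER
    if y_c > y_s:
        return UPPER
    return UNKNOWN


def _extended_overlap(screw: BoundingBox, crown: BoundingBox, jaw: str) -> float:
    """Fraction of the crown box covered by the screw box after extending
    the screw box along y to the crown's far edge."""
    if jaw == LOWER:  # crown above the screw
        y0 = min(screw.y, crown.y)
        y1 = screw.y + screw.h
    else:             # upper jaw: crown below
        y0 = screw.y
        y1 = max(screw.y + screw.h, crown.y + crown.h)
    x_overlap = min(screw.x + screw.w, crown.x + crown.w) - max(screw.x, crown.x)
    y_overlap = min(y1, crown.y + crown.h) - max(y0, crown.y)
    if x_overlap <= 0 or y_overlap <= 0:
        return 0.0
    return (x_overlap * y_overlap) / crown.area


def _on_coronal_side(screw: BoundingBox, crown: BoundingBox, jaw: str) -> bool:
    if jaw == LOWER:
        return crown.center[1] < screw.center[1]
    return crown.center[1] > screw.center[1]


def associate(
    d: DetectionSet,
    jaw: str | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ImplantUnit]:
    """Pair each screw with at most one crown (maximum overlap wins,
    ties broken by nearest crown center). Screws without a valid crown
    are excluded from downstream processing."""
    if jaw is None:
        jaw = d.jaw if d.jaw != UNKNOWN else classify_jaw(d)
    if jaw not in (UPPER, LOWER):
        raise GatingError("jaw side unknown: image excluded from analysis")
    crowns = d.by_label(CROWN)
    units: list[ImplantUnit] = []
    for screw in sorted(d.by_label(SCREW), key=lambda b: (b.x, b.y)):
        best: tuple[float, float, BoundingBox] | None = None
        for crown in crowns:
            if not _on_coronal_side(screw, crown, jaw):
                continue
            frac = _extended_overlap(screw, crown, jaw)
            if frac <= config.overlap_min:
                continue
            dist = float(np.hypot(
                screw.center[0] - crown.center[0],
                screw.center[1] - crown.center[1],
            ))
            key = (frac, -dist, crown)
            if best is None or key[:2] > best[:2]:
                best = key
        if best is not None:
            units.append(ImplantUnit(screw, best[2], best[0]))
    return units


def contrast_quality(
    r: Radiograph,
    units: list[ImplantUnit],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> QualityMetric:
    """Population std-dev of intensities in the union of the unit boxes,
    normalized to [0, 1] by sigma_max."""
    if not units:
        raise ParameterError("contrast_quality needs at least one implant unit")
    mask = np.zeros(r.pixels.shape, dtype=bool)
    for unit in units:
        for box in (unit.screw_box, unit.crown_box):
            b = box.clamped(r.width, r.height)
            mask[int(b.y):int(np.ceil(b.y + b.h)),
                 int(b.x):int(np.ceil(b.x + b.w))] = True
    sigma_raw = float(r.pixels[mask].std())
    sigma_norm = min(1.0, sigma_raw / config.sigma_max)
    return QualityMetric(
        sigma_raw=sigma_raw,
        sigma_norm=sigma_norm,
        high_contrast=sigma_norm >= config.contrast_threshold,
    )
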
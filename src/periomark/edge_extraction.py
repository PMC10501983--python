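"""Image enhancement and screw-restricted edge maps.

The measurement pipeline always applies a gamma adjustment (gamma = 1.5)
before Canny: it pushes mid-gray tissue darker while the bright metallic
parts keep their level, sharpening the implant/tissue step. On
low-contrast images an additional linear stretch maps [m - s, m + s]
onto [0, 255] (m, s = image mean and std-dev) beforehand.

Canny thresholds are derived from the smoothed gradient-magnitude
distribution (high = a percentile, low = a ratio of high) since no fixed
thresholds work across exposure levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _sk_canny
from skimage.morphology import dilation as _sk_dilation

from .config import DEFAULT_CONFIG, PipelineConfig
from .detection_gate import ImplantUnit
from .errors import EnhancementError, ParameterError
from .radiograph_io import BoundingBox, Radiograph


@dataclass
class EdgeMap:
    """Binary edge grid with a provenance tag (raw / dilated / masked)."""

    data: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.data.sum())


def enhance_gamma(r: Radiograph, gamma: float = 1.5) -> Radiograph:
    """out = round(255 * (in / 255) ** gamma); endpoints 0 and 255 are
    fixed and the mapping is monotone non-decreasing."""
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    out = np.floor(255.0 * (r.pixels / 255.0) ** gamma + 0.5)
    return Radiograph(out, r.mm_per_px_vertical, r.source_id)


def enhance_linear(r: Radiograph) -> Radiograph:
    """Affine map of [m - s, m + s] onto [0, 255], clamped outside."""
    m = float(r.pixels.mean())
    s = float(r.pixels.std())
    if s == 0:
        raise EnhancementError("constant image: linear enhancement undefined")
    out = (r.pixels - (m - s)) * (255.0 / (2.0 * s))
    out = np.clip(np.floor(out + 0.5), 0, 255)
    return Radiograph(out, r.mm_per_px_vertical, r.source_id)


def canny_edges(
    r: Radiograph, config: PipelineConfig = DEFAULT_CONFIG
) -> EdgeMap:
    """Canny edge map with data-driven hysteresis thresholds.

    high = ``canny_high_pct`` percentile of the Gaussian-smoothed
    gradient magnitude (positive part), low = ``canny_low_ratio`` * high.
    """
    img = r.pixels
    grad = ndimage.gaussian_gradient_magnitude(img, sigma=config.canny_sigma)
    positive = grad[grad > 1e-12]
    if positive.size == 0:  # constant image
        return EdgeMap(np.zeros(img.shape, dtype=bool), provenance="raw")
    high = float(np.percentile(positive, config.canny_high_pct))
    low = config.canny_low_ratio * high
    edges = _sk_canny(
        img, sigma=config.canny_sigma, low_threshold=low, high_threshold=high
    )
    return EdgeMap(edges, provenance="raw")


def expand_box(
    box: BoundingBox, fraction: float, width: int, height: int
) -> tuple[int, int, int, int]:
    """Grow a box by ``fraction`` per dimension (half per side), with
    floor on the top-left shift and ceil on the size growth so the
    expanded box always contains the original. Returns integer
    (x0, y0, w, h) clamped to the image."""
    eps = 1e-9  # guard the ceil against float artifacts (50*1.1 = 55.0...01)
    dx = box.w * fraction / 2.0
    dy = box.h * fraction / 2.0
    x0 = int(np.floor(box.x - dx + eps))
    y0 = int(np.floor(box.y - dy + eps))
    w = int(np.ceil(box.w * (1.0 + fraction) - eps))
    h = int(np.ceil(box.h * (1.0 + fraction) - eps))
    x1 = min(x0 + w, width)
    y1 = min(y0 + h, height)
    x0 = max(x0, 0)
    y0 = max(y0, 0)
    return x0, y0, x1 - x0, y1 - y0


def screw_roi_edges(
    e: EdgeMap,
    units: list[ImplantUnit],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EdgeMap:
    """Keep edges inside the screw boxes expanded by 10% per dimension,
    then dilate with a 3x3 structuring element to emphasize and bridge
    the retained edge chains."""
    if not units:
        raise ParameterError("screw_roi_edges needs at least one implant unit")
    height, width = e.data.shape
    mask = np.zeros_like(e.data)
    for unit in units:
        x0, y0, w, h = expand_box(unit.screw_box, config.roi_expand, width, height)
        if w <= 0 or h <= 0:
            warnings.warn("expanded screw box degenerate after clamping; skipped")
            continue
        mask[y0:y0 + h, x0:x0 + w] = True
    masked = e.data & mask
    dilated = _sk_dilation(masked, footprint=np.ones(config.dilate_se, dtype=bool))
    return EdgeMap(dilated & mask, provenance="masked")
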
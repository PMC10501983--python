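"""Edge description: Hough lines, segment extraction, grouping, and
least-squares polynomial fits.

The screw edges are near-vertical curved lines. A standard Hough
transform (rho = x*cos(theta) + y*sin(theta), accumulator bins of
1 pixel x 1 degree) finds the dominant straight lines; several
piecewise lines cover one curved edge, so their in-band edge pixels are
merged back into connected groups, and each group receives

* a straight-line fit (used to define the perpendicular scan direction),
* a polynomial fit x = a + b*y + c*y**2 (the edge curve proper).

x is modeled as a function of y throughout: the target edges are
oriented toward the vertical, where y -> x is the well-posed direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage
from skimage.measure import label as _sk_label
from skimage.morphology import dilation as _sk_dilation

from .config import DEFAULT_CONFIG, PipelineConfig
from .edge_extraction import EdgeMap
from .errors import DescriptionError, FitError

#: relative MSE improvement a higher degree must deliver to win the
#: degree selection; nested least squares always reduces MSE slightly,
#: so "minimum MSE" needs a tie band to be meaningful.
DEGREE_REL_TOL = 0.05
_ABS_TOL = 1e-9


@dataclass(frozen=True)
class HoughLine:
    """One accumulator peak: rho in px, theta in degrees in [0, 180)."""

    rho: float
    theta: float
    votes: int

    @property
    def is_vertical(self) -> bool:
        return np.sin(np.deg2rad(self.theta)) == 0.0

    @property
    def angle_from_horizontal(self) -> float:
        """Slope angle of the *line* (not its normal) vs the x-axis, in
        [0, 90]; 90 for a vertical line."""
        return abs(90.0 - (self.theta % 180.0))


@dataclass
class EdgeGroup:
    """A labeled cloud of edge pixels belonging to one screw edge."""

    label: int
    xs: np.ndarray
    ys: np.ndarray

    @property
    def y_min(self) -> int:
        return int(self.ys.min())

    @property
    def y_max(self) -> int:
        return int(self.ys.max())

    @property
    def size(self) -> int:
        return len(self.xs)


@dataclass
class PolynomialFit:
    """x = coeffs[0] + coeffs[1]*y + coeffs[2]*y**2 + ... with the mean
    squared x-residual of the fit."""

    degree: int
    coeffs: tuple[float, ...]
    mse: float

    def __call__(self, y) -> np.ndarray | float:
        return npoly.polyval(y, self.coeffs)

    def derivative(self, y) -> np.ndarray | float:
        der = npoly.polyder(self.coeffs)
        return npoly.polyval(y, der)


@dataclass
class FittedEdge:
    group: EdgeGroup
    line: PolynomialFit          # degree 1
    curve: PolynomialFit         # degree 2
    side: str = ""               # "left" | "right" of its screw
    implant_id: int = -1


# ---------------------------------------------------------------------------
# Hough transform
# ---------------------------------------------------------------------------

def hough_accumulate(
    e: EdgeMap,
    n_peaks: int = DEFAULT_CONFIG.hough_n_peaks,
    min_votes: int = DEFAULT_CONFIG.hough_min_votes,
) -> list[HoughLine]:
    """Accumulate votes in (rho, theta) bins of 1 px x 1 degree and
    return up to ``n_peaks`` local maxima with at least ``min_votes``
    votes, in descending vote order.

    A bin is a peak when its count is >= all 8 neighbors; ties among
    peaks are broken by (votes desc, rho asc, theta asc) so the result
    is deterministic.
    """
    ys, xs = np.nonzero(e.data)
    if len(xs) == 0:
        raise DescriptionError("hough_accumulate needs a non-empty edge map")
    acc, offset = _accumulator(xs, ys, e.data.shape)
    return _peaks(acc, offset, n_peaks, min_votes)


def _accumulator(xs, ys, shape) -> tuple[np.ndarray, int]:
    height, width = shape
    thetas = np.deg2rad(np.arange(180))
    offset = int(np.ceil(np.hypot(height - 1, width - 1)))
    rho = np.rint(
        xs[:, None] * np.cos(thetas)[None, :]
        + ys[:, None] * np.sin(thetas)[None, :]
    ).astype(np.int64)
    idx = (rho + offset) * 180 + np.arange(180)[None, :]
    counts = np.bincount(idx.ravel(), minlength=(2 * offset + 1) * 180)
    return counts.reshape(2 * offset + 1, 180), offset


def _peaks(acc, offset, n_peaks, min_votes) -> list[HoughLine]:
    local_max = acc >= ndimage.maximum_filter(acc, size=3, mode="constant")
    cand = np.argwhere(local_max & (acc >= min_votes))
    order = sorted(
        (( -acc[r, t], r - offset, t) for r, t in cand),
    )
    return [
        HoughLine(rho=float(rho), theta=float(theta), votes=int(-neg))
        for neg, rho, theta in order[:n_peaks]
    ]


def hough_to_slope_intercept(h: HoughLine) -> tuple[float, float]:
    """m = -cos(theta)/sin(theta), d = rho/sin(theta). A vertical line
    (sin(theta) = 0) has no slope-intercept form and raises; callers
    represent it as x = rho."""
    theta = np.deg2rad(h.theta)
    s, c = np.sin(theta), np.cos(theta)
    if s == 0.0:
        raise FitError("vertical line: represent as x = rho")
    return (-c / s, h.rho / s)


def filter_by_slope(
    lines: list[HoughLine], min_angle: float = DEFAULT_CONFIG.slope_min_deg
) -> list[HoughLine]:
    """Discard lines tending toward the horizontal: keep only lines
    whose slope angle from the x-axis is >= ``min_angle`` degrees."""
    return [h for h in lines if h.angle_from_horizontal >= min_angle]


# ---------------------------------------------------------------------------
# segments and groups
# ---------------------------------------------------------------------------

def extract_segments(
    e: EdgeMap,
    lines: list[HoughLine],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EdgeMap:
    """Keep edge pixels within ``line_band`` px of any retained line,
    split along-line runs at gaps > ``max_gap`` px, and drop runs whose
    extent is below ``min_seg_len`` px. The union over lines describes
    the curved edges piecewise."""
    if not lines:
        raise DescriptionError("extract_segments needs >= 1 retained line")
    ys, xs = np.nonzero(e.data)
    if len(xs) == 0:
        raise DescriptionError("empty edge map")
    keep = np.zeros(len(xs), dtype=bool)
    for line in lines:
        theta = np.deg2rad(line.theta)
        dist = np.abs(xs * np.cos(theta) + ys * np.sin(theta) - line.rho)
        in_band = dist <= config.line_band
        if not in_band.any():
            continue
        # coordinate along the line direction
        t = -xs[in_band] * np.sin(theta) + ys[in_band] * np.cos(theta)
        order = np.argsort(t, kind="stable")
        t_sorted = t[order]
        idx_sorted = np.flatnonzero(in_band)[order]
        breaks = np.flatnonzero(np.diff(t_sorted) > config.max_gap)
        start = 0
        for stop in list(breaks + 1) + [len(t_sorted)]:
            if t_sorted[stop - 1] - t_sorted[start] >= config.min_seg_len:
                keep[idx_sorted[start:stop]] = True
            start = stop
    if not keep.any():
        raise DescriptionError("no edge pixels retained by any line")
    out = np.zeros_like(e.data)
    out[ys[keep], xs[keep]] = True
    return EdgeMap(out, provenance="segments")


def group_and_label(
    segs: EdgeMap,
    roi_edges: EdgeMap,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[EdgeGroup]:
    """Dilate the segment map horizontally (1x5 structuring element) to
    close small lateral gaps, label connected components
    (8-connectivity), and intersect each labeled region with the ROI
    edge map to recover the full pixel alignments. Groups smaller than
    ``min_group_px`` pixels are dropped."""
    if segs.count == 0:
        raise DescriptionError("empty segment map")
    dilated = _sk_dilation(
        segs.data, footprint=np.ones(config.group_dilate_se, dtype=bool)
    )
    labels = _sk_label(dilated, connectivity=2)
    masked = np.where(roi_edges.data, labels, 0)
    groups: list[EdgeGroup] = []
    for lab in np.unique(masked):
        if lab == 0:
            continue
        ys, xs = np.nonzero(masked == lab)
        if len(xs) < config.min_group_px:
            continue
        # groups describe near-vertical edges: require a vertical extent
        # at least as long as a minimal segment
        if ys.max() - ys.min() < config.min_seg_len:
            continue
        groups.append(EdgeGroup(label=int(lab), xs=xs, ys=ys))
    if not groups:
        raise DescriptionError("no edge groups survived labeling")
    groups.sort(key=lambda g: (float(g.xs.mean()), g.label))
    for i, g in enumerate(groups, start=1):
        g.label = i
    return groups


# ---------------------------------------------------------------------------
# polynomial fits
# ---------------------------------------------------------------------------

def fit_edge(g: EdgeGroup, degree: int) -> PolynomialFit:
    """Least-squares fit of x as a polynomial in y over the group."""
    if degree not in (1, 2, 3):
        raise FitError(f"degree must be 1, 2 or 3, got {degree}")
    if g.size <= degree + 1:
        raise FitError("not enough pixels for the requested degree")
    if len(np.unique(g.ys)) <= degree:
        raise FitError("rank-deficient fit: too few distinct y values")
    coeffs = npoly.polyfit(g.ys.astype(float), g.xs.astype(float), degree)
    resid = g.xs - npoly.polyval(g.ys.astype(float), coeffs)
    return PolynomialFit(
        degree=degree, coeffs=tuple(float(c) for c in coeffs),
        mse=float(np.mean(resid ** 2)),
    )


def select_degree(g: EdgeGroup, max_degree: int = 3) -> PolynomialFit:
    """Fit degrees 1..max_degree and keep the minimum-MSE fit, with ties
    broken toward the lowest degree.

    "Tie" means the higher degree improves the MSE by less than
    ``DEGREE_REL_TOL`` relatively (or the MSE is already ~0): nested
    models always reduce the raw MSE, so a literal argmin would always
    return the highest degree.
    """
    best: PolynomialFit | None = None
    for degree in range(1, max_degree + 1):
        try:
            fit = fit_edge(g, degree)
        except FitError:
            if best is None:
                raise
            break
        if best is None:
            best = fit
        elif best.mse > _ABS_TOL and fit.mse < best.mse * (1.0 - DEGREE_REL_TOL):
            best = fit
    assert best is not None
    return best


def describe_edges(
    roi_edges: EdgeMap,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[FittedEdge]:
    """Full description stage: Hough peaks -> slope filter -> segment
    extraction -> grouping -> degree-1 and degree-2 fits per group."""
    lines = hough_accumulate(
        roi_edges, n_peaks=config.hough_n_peaks, min_votes=config.hough_min_votes
    )
    lines = filter_by_slope(lines, config.slope_min_deg)
    if not lines:
        raise DescriptionError("no near-vertical Hough lines found")
    segs = extract_segments(roi_edges, lines, config)
    groups = group_and_label(segs, roi_edges, config)
    edges = []
    for g in groups:
        try:
            line = fit_edge(g, 1)
            curve = fit_edge(g, 2)
        except FitError:
            continue
        edges.append(FittedEdge(group=g, line=line, curve=curve))
    if not edges:
        raise DescriptionError("no fittable edge groups")
    return edges
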
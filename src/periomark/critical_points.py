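"""Perpendicular intensity scanning and critical-point detection.

For each fitted edge the image is traversed along the degree-2 curve
from the apical end toward the crown (y_max -> y_min in the lower jaw,
the reverse in the upper jaw). At each step a short intensity profile is
read on both sides of the edge along the unit normal of the straight
line fit; sampling starts a few pixels away from the line (so the
bright metallic edge itself is skipped) and averages ``extent`` pixels
per side with bilinear interpolation.

With L and R the left/right side means and D = L - R, the accumulated
profile takes the darker flank::

    Cum(y) = L  if D < 0  else  R        (elementwise min(L, R))

The first critical point (bone-defect onset) is where Cum drops
abruptly below its overall mean and stays there; the second (crown
entry) is found by switching to the opposite -- implant/crown -- side
and waiting for ``run_len`` consecutive samples clearly above the
reference level r_av measured just past the first point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, PipelineConfig
from .edge_description import FittedEdge
from .errors import ScanError
from .radiograph_io import LOWER, BoundingBox, Radiograph

STATUS_BOTH = "both"
STATUS_FIRST_ONLY = "first_only"
STATUS_NONE = "none"


@dataclass
class ProfileScan:
    """Per-step records of one perpendicular traversal.

    ``ys``/``xs`` follow traversal order (index 0 = apical start).
    """

    ys: np.ndarray
    xs: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.left - self.right

    @property
    def cum(self) -> np.ndarray:
        """Phase-1 accumulated profile: the darker side at each step."""
        return np.where(self.diff < 0, self.left, self.right)

    def __len__(self) -> int:
        return len(self.ys)

    def phase1_side(self, p: int | None = None) -> str:
        """Which side ("L"/"R") the min rule picked most often up to p."""
        stop = len(self) if p is None else p + 1
        d = self.diff[:stop]
        return "L" if (d < 0).sum() > (d > 0).sum() else "R"

    def opposite_side_values(self, p: int | None = None) -> np.ndarray:
        """Samples of the side *opposite* the phase-1 min side -- the
        implant/crown flank used for crown-entry detection."""
        return self.right if self.phase1_side(p) == "L" else self.left


@dataclass
class CriticalPair:
    first: tuple[float, float] | None = None    # (x, y): bone-defect onset
    second: tuple[float, float] | None = None   # (x, y): crown entry
    r_av: float | None = None
    status: str = STATUS_NONE
    first_index: int | None = None
    second_index: int | None = None


def scan_profile(
    r: Radiograph,
    edge: FittedEdge,
    jaw: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ProfileScan:
    """Traverse the edge curve in unit y-steps from the apical end and
    sample both flanks along the perpendicular of the straight-line fit.
    Off-grid samples are bilinearly interpolated and border-clamped."""
    y_lo, y_hi = edge.group.y_min, edge.group.y_max
    if jaw == LOWER:
        ys = np.arange(y_hi, y_lo - 1, -1, dtype=float)
    else:
        ys = np.arange(y_lo, y_hi + 1, dtype=float)
    xs = np.asarray(edge.curve(ys), dtype=float)
    outside = (xs < 0) | (xs > r.width - 1)
    if outside.mean() > 0.5:
        raise ScanError("fitted curve lies outside the image for >50% of steps")

    b = edge.line.coeffs[1]  # slope of x = a + b*y
    norm = np.sqrt(1.0 + b * b)
    nx, ny = 1.0 / norm, -b / norm  # unit normal pointing toward +x
    offsets = config.scan_start_offset + np.arange(config.scan_extent)

    def side_means(sign: float) -> np.ndarray:
        px = xs[:, None] + sign * offsets[None, :] * nx
        py = ys[:, None] + sign * offsets[None, :] * ny
        vals = ndimage.map_coordinates(
            r.pixels, [py.ravel(), px.ravel()], order=1, mode="nearest"
        ).reshape(px.shape)
        return vals.mean(axis=1)

    return ProfileScan(ys=ys, xs=xs, left=side_means(-1.0), right=side_means(+1.0))


def _first_sub_mean_run(
    cum: np.ndarray, persist: int, min_drop: float
) -> int | None:
    """First index opening an abrupt, sustained drop of the profile.

    A candidate opens ``persist`` consecutive samples at least
    ``min_drop`` below the profile mean; it is accepted only if the
    remaining profile from the candidate onward stays depressed on
    average (mean below the overall mean by at least ``min_drop``/2).
    A local texture dip leaves the rest of the profile at its normal
    level and is rejected; a true tissue transition keeps it low until
    the crown region. min_drop = 0 recovers a plain below-mean rule.
    """
    mu = float(cum.mean())
    below = cum < mu - min_drop
    if persist <= 1:
        hits = np.flatnonzero(below)
    else:
        window = np.ones(persist, dtype=int)
        runs = np.convolve(below.astype(int), window, mode="valid") == persist
        hits = np.flatnonzero(runs)
    for p in hits:
        if float(cum[p:].mean()) < mu - min_drop / 2.0:
            return int(p)
    return None


def first_critical_point(
    scan: ProfileScan,
    edge: FittedEdge,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, float, int] | None:
    """Detect the bone-defect onset on the Cum profile.

    Returns (x_f, y_f, p) with p the traversal index, or None when the
    profile shows no abrupt decrease (no measurable resorption).
    """
    p = _first_sub_mean_run(scan.cum, config.scan_persist, config.scan_min_drop)
    if p is None:
        return None
    y_f = float(scan.ys[p])
    x_f = float(edge.curve(y_f))
    return x_f, y_f, p


def reference_level(
    scan: ProfileScan, p: int, run_len: int = DEFAULT_CONFIG.scan_run_len
) -> float | None:
    """Average the ``run_len`` implant-side samples just past the first
    critical point to obtain the reference intensity r_av. None when
    fewer than ``run_len`` samples remain (status first_only)."""
    if p + run_len >= len(scan):
        return None
    vals = scan.opposite_side_values(p)[p + 1:p + 1 + run_len]
    return float(vals.mean())


def _first_bright_run(vals: np.ndarray, threshold: float, run_len: int) -> int | None:
    above = vals > threshold
    if len(above) < run_len:
        return None
    runs = np.convolve(above.astype(int), np.ones(run_len, dtype=int),
                       mode="valid") == run_len
    hits = np.flatnonzero(runs)
    return int(hits[0]) if hits.size else None


def second_critical_point(
    scan: ProfileScan,
    edge: FittedEdge,
    p: int,
    r_av: float,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, float, int] | None:
    """Detect crown entry past the first critical point.

    The traversal continues on the implant/crown flank (the side
    opposite the phase-1 min side); the crown is entered at the first
    run of ``run_len`` consecutive samples all above
    ``run_factor * r_av``, and the second critical point takes the y of
    the first sample of that run.
    """
    vals = scan.opposite_side_values(p)[p + 1:]
    rel = _first_bright_run(vals, config.run_factor * r_av, config.scan_run_len)
    if rel is None:
        return None
    idx = p + 1 + rel
    y_s = float(scan.ys[idx])
    x_s = float(edge.curve(y_s))
    return x_s, y_s, idx


def _inside_any(point: tuple[float, float], boxes) -> bool:
    x, y = point
    return any(
        b.x <= x < b.x + b.w and b.y <= y < b.y + b.h for b in boxes
    )


def detect_edge_critical_pair(
    r: Radiograph,
    edge: FittedEdge,
    jaw: str,
    crowns: list[BoundingBox] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CriticalPair:
    """Compose scan -> first point -> reference level -> second point.

    When ``config.verify_crown`` is set and the second point lies inside
    no crown box, the pair is downgraded to first_only.
    """
    scan = scan_profile(r, edge, jaw, config)
    first = first_critical_point(scan, edge, config)
    if first is None:
        return CriticalPair(status=STATUS_NONE)
    x_f, y_f, p = first
    pair = CriticalPair(
        first=(x_f, y_f), status=STATUS_FIRST_ONLY, first_index=p
    )
    r_av = reference_level(scan, p, config.scan_run_len)
    if r_av is None:
        return pair
    pair.r_av = r_av
    second = second_critical_point(scan, edge, p, r_av, config)
    if second is None:
        return pair
    x_s, y_s, idx = second
    if config.verify_crown and crowns and not _inside_any((x_s, y_s), crowns):
        return pair
    pair.second = (x_s, y_s)
    pair.second_index = idx
    pair.status = STATUS_BOTH
    return pair
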
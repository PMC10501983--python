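"""Bone-resorption quantities: arc lengths, percentages, severity
classes and millimetre conversion.

The resorbed span is the piece of the fitted edge curve between the two
critical points; its arc length relative to the full curve length gives
the resorption percentage. Severity bands: normal (<= 10%), early
(10-25%], moderate (25-50%), severe (>= 50%). Vertical pixel distances
convert to millimetres with the device calibration (0.063 mm/px by
default, established from implants of known length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .critical_points import STATUS_BOTH, CriticalPair
from .edge_description import FittedEdge, PolynomialFit
from .errors import ParameterError
from .radiograph_io import DEFAULT_MM_PER_PX

SEVERITY_UNDETECTED = "undetected"


def arc_length(curve: PolynomialFit, y_a: float, y_b: float) -> float:
    """Discrete arc length of x(y) over [y_a, y_b]: unit y-steps with
    the derivative evaluated at step midpoints, plus a fractional final
    step. Integer endpoints make the sum exactly additive."""
    if y_a > y_b:
        raise ParameterError("arc_length requires y_a <= y_b")
    if y_a == y_b:
        return 0.0
    steps = np.arange(y_a, y_b, 1.0)
    widths = np.minimum(steps + 1.0, y_b) - steps
    mids = steps + widths / 2.0
    slope = np.asarray(curve.derivative(mids), dtype=float)
    return float(np.sum(widths * np.sqrt(1.0 + slope ** 2)))


def resorption_percentage(
    edge: FittedEdge,
    pair: CriticalPair,
    known_length_mm: float | None = None,
    mm_per_px_vertical: float = DEFAULT_MM_PER_PX,
) -> tuple[float, float]:
    """(percentage, loss_px) for a detected pair.

    The numerator is the curve arc between the two critical points. The
    denominator defaults to the arc over the visible fitted span
    [y_min, y_max]; when the physical implant length is known it can be
    supplied in mm (handles occluded apical tips) and is converted with
    the vertical calibration.
    """
    if pair.status != STATUS_BOTH:
        raise ParameterError("resorption percentage needs both critical points")
    y_f = pair.first[1]
    y_s = pair.second[1]
    lo, hi = sorted((y_f, y_s))
    loss_px = arc_length(edge.curve, lo, hi)
    if known_length_mm is not None:
        denom = known_length_mm / mm_per_px_vertical
    else:
        denom = arc_length(edge.curve, edge.group.y_min, edge.group.y_max)
    if denom <= 0:
        raise ParameterError("degenerate curve span")
    pct = float(np.clip(100.0 * loss_px / denom, 0.0, 100.0))
    return pct, loss_px


def classify_severity(p: float) -> str:
    """normal (<= 10), early (10, 25], moderate (25, 50), severe (>= 50).

    The closed endpoints follow the explicit <= / >= marks of the
    banding definition; the interior bands are half-open accordingly.
    """
    if not 0.0 <= p <= 100.0:
        raise ParameterError(f"percentage out of range: {p}")
    if p <= 10.0:
        return "normal"
    if p <= 25.0:
        return "early"
    if p < 50.0:
        return "moderate"
    return "severe"


def px_to_mm(v: float, calib: float = DEFAULT_MM_PER_PX) -> float:
    """Vertical pixels -> millimetres, reported at 2 decimals."""
    if calib <= 0:
        raise ParameterError("calibration must be > 0")
    return round(v * calib, 2)


@dataclass
class EdgeMeasurement:
    """Per-edge row of a resorption report."""

    edge_id: int
    implant_id: int
    side: str
    status: str
    percentage: float | None = None
    severity: str = SEVERITY_UNDETECTED
    loss_px: float | None = None
    loss_mm: float | None = None
    first: tuple[float, float] | None = None
    second: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "edge_id": self.edge_id,
            "implant_id": self.implant_id,
            "side": self.side,
            "status": self.status,
            "percentage": self.percentage,
            "severity": self.severity,
            "loss_px": self.loss_px,
            "loss_mm": self.loss_mm,
            "x_first": None if self.first is None else self.first[0],
            "y_first": None if self.first is None else self.first[1],
            "x_second": None if self.second is None else self.second[0],
            "y_second": None if self.second is None else self.second[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EdgeMeasurement":
        first = None if d.get("x_first") is None else (d["x_first"], d["y_first"])
        second = None if d.get("x_second") is None else (d["x_second"], d["y_second"])
        return cls(
            edge_id=d["edge_id"], implant_id=d["implant_id"], side=d["side"],
            status=d["status"], percentage=d.get("percentage"),
            severity=d.get("severity", SEVERITY_UNDETECTED),
            loss_px=d.get("loss_px"), loss_mm=d.get("loss_mm"),
            first=first, second=second,
        )


@dataclass
class ResorptionReport:
    """Per-image measurement summary."""

    source_id: str = ""
    jaw: str = "unknown"
    sigma_norm: float | None = None
    high_contrast: bool | None = None
    edges: list[EdgeMeasurement] = field(default_factory=list)

    @property
    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.status] = counts.get(e.status, 0) + 1
        return counts

    @property
    def measured_percentages(self) -> list[float]:
        return [e.percentage for e in self.edges if e.percentage is not None]

    @property
    def no_resorption_detected(self) -> bool:
        return len(self.measured_percentages) == 0

    def to_dict(self) -> dict:
        pcts = self.measured_percentages
        return {
            "source_id": self.source_id,
            "jaw": self.jaw,
            "sigma_norm": self.sigma_norm,
            "high_contrast": self.high_contrast,
            "status_counts": self.status_counts,
            "max_percentage": max(pcts) if pcts else None,
            "min_percentage": min(pcts) if pcts else None,
            "no_resorption_detected": self.no_resorption_detected,
            "edges": [e.to_dict() for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResorptionReport":
        return cls(
            source_id=d.get("source_id", ""),
            jaw=d.get("jaw", "unknown"),
            sigma_norm=d.get("sigma_norm"),
            high_contrast=d.get("high_contrast"),
            edges=[EdgeMeasurement.from_dict(e) for e in d.get("edges", [])],
        )


def build_report(
    source_id: str,
    jaw: str,
    quality,
    edges: list[FittedEdge],
    pairs: list[CriticalPair],
    mm_per_px_vertical: float = DEFAULT_MM_PER_PX,
    known_length_mm: float | None = None,
) -> ResorptionReport:
    """Assemble per-edge measurements into a report."""
    rows = []
    for i, (edge, pair) in enumerate(zip(edges, pairs), start=1):
        row = EdgeMeasurement(
            edge_id=i, implant_id=edge.implant_id, side=edge.side,
            status=pair.status, first=pair.first, second=pair.second,
        )
        if pair.status == STATUS_BOTH:
            pct, loss_px = resorption_percentage(
                edge, pair, known_length_mm, mm_per_px_vertical
            )
            row.percentage = pct
            row.severity = classify_severity(pct)
            row.loss_px = loss_px
            row.loss_mm = px_to_mm(loss_px, mm_per_px_vertical)
        rows.append(row)
    return ResorptionReport(
        source_id=source_id, jaw=jaw,
        sigma_norm=None if quality is None else quality.sigma_norm,
        high_contrast=None if quality is None else quality.high_contrast,
        edges=rows,
    )
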
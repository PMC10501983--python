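"""End-to-end analysis: gate -> extract -> describe -> critical points
-> resorption report.

The stages and their order:

1. jaw classification and crown-screw association (gating; images
   without a valid pair are rejected);
2. contrast quality; low-contrast images get the linear enhancement
   before the always-on gamma adjustment;
3. Canny edges restricted to the expanded screw boxes;
4. Hough-guided grouping and polynomial fitting of the screw edges,
   each group assigned to its screw and labeled left/right;
5. perpendicular intensity scans and critical-point detection, always
   on the *original* intensity image: the profile thresholds are
   defined on the acquisition's 8-bit scale, and a contrast stretch
   saturates the metallic parts it needs to tell apart;
6. percentages, severity classes and millimetre conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import critical_points, detection_gate, edge_description, edge_extraction
from .config import DEFAULT_CONFIG, PipelineConfig
from .detection_gate import ImplantUnit, QualityMetric
from .edge_description import FittedEdge
from .errors import GatingError
from .radiograph_io import CROWN, DetectionSet, Radiograph
from .resorption import ResorptionReport, build_report

logger = logging.getLogger("periomark")


@dataclass
class AnalysisArtifacts:
    """Intermediate products of one analysis, for inspection/evaluation."""

    jaw: str = ""
    units: list[ImplantUnit] = field(default_factory=list)
    quality: QualityMetric | None = None
    edges: list[FittedEdge] = field(default_factory=list)
    pairs: list = field(default_factory=list)


def _assign_edges_to_units(
    edges: list[FittedEdge],
    units: list[ImplantUnit],
    width: int,
    height: int,
    config: PipelineConfig,
) -> list[FittedEdge]:
    """Attach each edge group to the screw whose expanded box contains
    it (nearest box-center x on ambiguity) and label its side."""
    assigned = []
    for edge in edges:
        gx = float(edge.group.xs.mean())
        gy = float(edge.group.ys.mean())
        best, best_dist = None, None
        for i, unit in enumerate(units):
            x0, y0, w, h = edge_extraction.expand_box(
                unit.screw_box, config.roi_expand, width, height
            )
            if not (x0 <= gx < x0 + w and y0 <= gy < y0 + h):
                continue
            cx = unit.screw_box.center[0]
            dist = abs(gx - cx)
            if best is None or dist < best_dist:
                best, best_dist = i, dist
        if best is None:
            logger.debug("edge group %d outside every screw box", edge.group.label)
            continue
        edge.implant_id = best
        edge.side = "left" if gx < units[best].screw_box.center[0] else "right"
        assigned.append(edge)
    return assigned


def analyze(
    r: Radiograph,
    detections: DetectionSet,
    config: PipelineConfig = DEFAULT_CONFIG,
    known_length_mm: float | None = None,
) -> tuple[ResorptionReport, AnalysisArtifacts]:
    """Measure marginal bone loss on one radiograph.

    Raises :class:`GatingError` when no valid crown-screw unit exists,
    :class:`DescriptionError` when no screw edge can be described, and
    :class:`ScanError` when a profile scan leaves the image.
    """
    art = AnalysisArtifacts()
    jaw = detection_gate.classify_jaw(detections)
    if jaw not in ("upper", "lower"):
        raise GatingError("jaw unknown: missing class or mean-y tie")
    art.jaw = jaw
    art.units = detection_gate.associate(detections, jaw, config)
    if not art.units:
        raise GatingError("no crown-screw pair with sufficient overlap")
    art.quality = detection_gate.contrast_quality(r, art.units, config)
    logger.info(
        "jaw=%s units=%d sigma_norm=%.3f", jaw, len(art.units),
        art.quality.sigma_norm,
    )

    intensity = r
    if config.auto_enhance and not art.quality.high_contrast:
        intensity = edge_extraction.enhance_linear(r)
        logger.info("low contrast: linear enhancement applied")
    gamma_img = edge_extraction.enhance_gamma(intensity, config.gamma)

    edge_map = edge_extraction.canny_edges(gamma_img, config)
    roi = edge_extraction.screw_roi_edges(edge_map, art.units, config)
    edges = edge_description.describe_edges(roi, config)
    art.edges = _assign_edges_to_units(edges, art.units, r.width, r.height, config)

    crowns = [u.crown_box for u in art.units]
    for edge in art.edges:
        pair = critical_points.detect_edge_critical_pair(
            r, edge, jaw, crowns, config
        )
        art.pairs.append(pair)

    report = build_report(
        r.source_id, jaw, art.quality, art.edges, art.pairs,
        mm_per_px_vertical=r.mm_per_px_vertical,
        known_length_mm=known_length_mm,
    )
    return report, art
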
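"""Synthetic radiograph phantoms with full ground truth.

A phantom emulates the structures the measurement pipeline relies on:

* a bright threaded screw with near-vertical, slightly tapered edges
  (degree-2 curvature) under a small rotation (shear up to +-10 deg);
* a brighter crown adjacent at the coronal end, connected through a
  short neck so the screw edge continues a few pixels into the crown
  (as it does where prosthesis meets fixture);
* textured bone of intermediate intensity flanking the screw;
* a darker soft-tissue/defect band alongside each edge whose vertical
  extent encodes a known resorption fraction;
* Gaussian sensor noise.

Intensity ordering crown > screw > bone > defect mirrors the fact that
metallic implant and prosthesis limits show the highest levels in the
radiograph. Thread geometry is a sinusoidal edge perturbation plus
matching interior intensity bands (threads image as alternating bands
across the screw); the ground truth stores the smooth baseline
polynomials. Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .radiograph_io import (
    CROWN, LOWER, SCREW, UPPER,
    BoundingBox, DetectionSet, Radiograph, write_detections, write_image,
)
from .resorption import arc_length
from .edge_description import PolynomialFit


@dataclass(frozen=True)
class ImplantGeom:
    """Geometry of one implant, lower-jaw orientation (crown above)."""

    center_x: float = 205.0
    junction_y: float = 110.0        # screw-crown junction (coronal end)
    length_px: float = 160.0         # junction -> apex
    width_px: float = 36.0
    rotation_deg: float = 0.0        # shear angle of the long axis
    taper: float = 3e-4              # |c| of the edge parabolas (px^-1)
    thread_amplitude_px: float = 2.0
    thread_period_px: float = 8.0
    defect_fraction: float = 0.2     # per-side resorbed share of length
    crown_flare_px: float = 14.0     # crown half-width beyond the screw
    crown_height_px: float = 40.0
    neck_height_px: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.defect_fraction <= 1.0:
            raise ParameterError("defect_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    width: int = 410
    height: int = 340
    jaw: str = LOWER
    implants: tuple[ImplantGeom, ...] = (
        ImplantGeom(center_x=140.0, rotation_deg=3.0),
        ImplantGeom(center_x=270.0, rotation_deg=-3.0),
    )
    crown_level: float = 245.0
    screw_level: float = 200.0
    bone_level: float = 120.0
    defect_level: float = 60.0
    thread_band_depth: float = 12.0
    thread_band_margin_px: float = 7.0   # bands show near the flanks only
    bone_texture: float = 8.0        # std-dev of the low-pass bone texture
    noise_sigma: float = 5.0
    defect_width_px: float = 26.0
    seed: int = 0


@dataclass
class TruthEdge:
    implant: int
    side: str                         # "left" | "right"
    coeffs: tuple[float, float, float]  # smooth baseline x = a + b*y + c*y^2
    domain: tuple[float, float]       # screw span (junction_y, apex_y)
    critical: list[tuple[float, float]]  # [(x_f, y_f), (x_s, y_s)] or []
    resorption_pct: float | None

    def curve(self) -> PolynomialFit:
        return PolynomialFit(degree=2, coeffs=self.coeffs, mse=0.0)

    def points(self, n: int = 12) -> np.ndarray:
        ys = np.linspace(self.domain[0], self.domain[1], n)
        xs = np.asarray(self.curve()(ys))
        return np.column_stack([xs, ys])


@dataclass
class PhantomTruth:
    jaw: str
    edges: list[TruthEdge] = field(default_factory=list)
    boxes: list[BoundingBox] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "jaw": self.jaw,
            "edges": [
                {
                    "implant": e.implant,
                    "side": e.side,
                    "coeffs": list(e.coeffs),
                    "domain": list(e.domain),
                    "points": e.points().tolist(),
                    "critical": [list(p) for p in e.critical],
                    "resorption_pct": e.resorption_pct,
                }
                for e in self.edges
            ],
            "boxes": [
                {"label": b.label, "x": b.x, "y": b.y, "w": b.w, "h": b.h,
                 "score": b.score}
                for b in self.boxes
            ],
        }


def _edge_polys(g: ImplantGeom) -> tuple[np.ndarray, np.ndarray]:
    """Smooth baseline coefficients (a, b, c) of the left and right edge
    in absolute image coordinates, x as a polynomial of y.

    Both edges share the shear slope b = tan(rotation); the taper bends
    them toward each other below the junction (screws narrow apically).
    """
    b = float(np.tan(np.deg2rad(g.rotation_deg)))
    y0 = g.junction_y
    half = g.width_px / 2.0
    # x(y) = x0 +- half + b*(y - y0) -+ c*(y - y0)^2, expanded in y
    out = []
    for sign in (-1.0, +1.0):
        c = -sign * g.taper
        a = g.center_x + sign * half + c * y0 * y0 - b * y0
        b_abs = b - 2.0 * c * y0
        out.append(np.array([a, b_abs, c]))
    return out[0], out[1]


def _poly_eval(coeffs: np.ndarray, y) -> np.ndarray:
    return coeffs[0] + coeffs[1] * y + coeffs[2] * y * y


def _flip_vertical(truth: PhantomTruth, height: int) -> PhantomTruth:
    """Mirror the truth for an upper-jaw phantom (image flipped)."""
    H = height - 1

    def flip_poly(coeffs):
        a, b, c = coeffs
        # substitute y -> H - y
        return (a + b * H + c * H * H, -(b + 2 * c * H), c)

    edges = []
    for e in truth.edges:
        lo, hi = e.domain
        edges.append(TruthEdge(
            implant=e.implant, side=e.side,
            coeffs=flip_poly(e.coeffs),
            domain=(H - hi, H - lo),
            critical=[(x, H - y) for x, y in e.critical],
            resorption_pct=e.resorption_pct,
        ))
    boxes = [
        dataclasses.replace(b, y=height - (b.y + b.h)) for b in truth.boxes
    ]
    return PhantomTruth(jaw=UPPER, edges=edges, boxes=boxes)


def render_phantom(spec: PhantomSpec) -> tuple[Radiograph, PhantomTruth]:
    """Render a phantom and its ground truth (deterministic per seed).

    Upper-jaw phantoms are rendered in lower-jaw orientation and
    mirrored vertically, truth included.
    """
    if spec.jaw not in (LOWER, UPPER):
        raise ParameterError(f"jaw must be upper or lower, got {spec.jaw!r}")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    # textured bone background
    raw = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(raw, sigma=3.0)
    texture = smooth * (spec.bone_texture / smooth.std())
    img = spec.bone_level + texture

    cols = np.arange(w, dtype=float)[None, :]
    truth = PhantomTruth(jaw=LOWER)

    for idx, g in enumerate(spec.implants):
        left, right = _edge_polys(g)
        y_j = g.junction_y
        y_apex = y_j + g.length_px
        y_neck = y_j - g.neck_height_px
        y_top = y_neck - g.crown_height_px
        if y_top < 0 or y_apex > h - 1:
            raise ParameterError("implant geometry exceeds the image")
        y_bone = y_j + g.defect_fraction * g.length_px

        ys = np.arange(h, dtype=float)[:, None]
        x_l = _poly_eval(left, ys)
        x_r = _poly_eval(right, ys)
        phase = 2.0 * np.pi * (ys - y_j) / g.thread_period_px
        thread = g.thread_amplitude_px * np.sin(phase)

        # soft-tissue / defect band alongside the resorbed section
        if g.defect_fraction > 0:
            drows = (ys >= y_j) & (ys < y_bone)
            dmask = drows & (
                ((cols >= x_l - spec.defect_width_px) & (cols < x_l))
                | ((cols > x_r) & (cols <= x_r + spec.defect_width_px))
            )
            img[dmask] = spec.defect_level

        # screw body; thread bands modulate the flanks (the projected
        # thread region) and fade smoothly toward the central axis, so
        # the interior carries no spurious intensity steps
        srows = (ys >= y_j) & (ys <= y_apex)
        smask = srows & (cols >= x_l - thread) & (cols <= x_r + thread)
        edge_dist = np.minimum(cols - x_l, x_r - cols)
        fade = np.exp(-np.maximum(edge_dist, 0.0) / spec.thread_band_margin_px)
        band = spec.thread_band_depth * (0.5 + 0.5 * np.sin(phase)) * fade
        img[smask] = (spec.screw_level - band)[smask]

        # neck (crown material continuing the screw edges) and crown flare
        nmask = (ys >= y_neck) & (ys < y_j) & (cols >= x_l) & (cols <= x_r)
        fmask = (
            (ys >= y_top) & (ys < y_neck)
            & (cols >= x_l - g.crown_flare_px) & (cols <= x_r + g.crown_flare_px)
        )
        img[nmask | fmask] = spec.crown_level

        # ground truth
        for side, coeffs in (("left", left), ("right", right)):
            curve = PolynomialFit(degree=2, coeffs=tuple(coeffs), mse=0.0)
            if g.defect_fraction > 0:
                crit = [
                    (float(curve(y_bone)), float(y_bone)),   # defect onset
                    (float(curve(y_j)), float(y_j)),         # crown entry
                ]
                pct = 100.0 * arc_length(curve, y_j, y_bone) / arc_length(
                    curve, y_j, y_apex
                )
            else:
                crit, pct = [], None
            truth.edges.append(TruthEdge(
                implant=idx, side=side, coeffs=tuple(float(v) for v in coeffs),
                domain=(float(y_j), float(y_apex)),
                critical=crit, resorption_pct=pct,
            ))

        # true boxes (bounding the rendered structures)
        sy = np.arange(int(np.ceil(y_j)), int(y_apex) + 1, dtype=float)
        sx_l = _poly_eval(left, sy) - g.thread_amplitude_px
        sx_r = _poly_eval(right, sy) + g.thread_amplitude_px
        truth.boxes.append(BoundingBox(
            SCREW, x=float(sx_l.min()), y=float(y_j),
            w=float(sx_r.max() - sx_l.min()), h=float(y_apex - y_j),
        ))
        cy = np.arange(int(np.ceil(y_top)), int(y_j) + 1, dtype=float)
        cx_l = _poly_eval(left, cy) - g.crown_flare_px
        cx_r = _poly_eval(right, cy) + g.crown_flare_px
        truth.boxes.append(BoundingBox(
            CROWN, x=float(cx_l.min()), y=float(y_top),
            w=float(cx_r.max() - cx_l.min()), h=float(y_j - y_top),
        ))

    img = img + rng.normal(scale=spec.noise_sigma, size=(h, w))
    img = np.clip(np.rint(img), 0, 255)

    if spec.jaw == UPPER:
        img = img[::-1].copy()
        truth = _flip_vertical(truth, h)

    return Radiograph(img, source_id=f"phantom-{spec.seed}"), truth


def emit_detections(
    truth: PhantomTruth,
    jitter: float = 2.0,
    score_range: tuple[float, float] = (0.6, 0.99),
    seed: int = 0,
    path: str | Path | None = None,
) -> DetectionSet:
    """Detector-like boxes: true boxes with uniform corner jitter and
    random confidence scores; optionally serialized as detections JSON."""
    if jitter < 0:
        raise ParameterError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    boxes = []
    for b in truth.boxes:
        dx0, dy0, dx1, dy1 = rng.uniform(-jitter, jitter, size=4)
        score = float(rng.uniform(*score_range))
        boxes.append(BoundingBox(
            b.label, x=b.x + dx0, y=b.y + dy0,
            w=max(b.w + dx1 - dx0, 1.0), h=max(b.h + dy1 - dy0, 1.0),
            score=score,
        ))
    dset = DetectionSet(boxes=boxes, jaw=truth.jaw)
    if path is not None:
        write_detections(dset, path)
    return dset


DIFFICULTIES = ("easy", "low_contrast", "rotated")


def _spec_for(difficulty: str, seed: int, rng: np.random.Generator) -> PhantomSpec:
    if difficulty not in DIFFICULTIES:
        raise ParameterError(f"difficulty must be one of {DIFFICULTIES}")
    max_rot = 10.0 if difficulty == "rotated" else 5.0
    implants = []
    for cx in (140.0, 270.0):
        implants.append(ImplantGeom(
            center_x=cx + float(rng.uniform(-8, 8)),
            rotation_deg=float(rng.uniform(-max_rot, max_rot)),
            defect_fraction=float(rng.uniform(0.12, 0.55)),
        ))
    spec = PhantomSpec(implants=tuple(implants), seed=seed)
    if difficulty == "low_contrast":
        spec = dataclasses.replace(
            spec, crown_level=225.0, screw_level=185.0, bone_level=150.0,
            defect_level=118.0, thread_band_depth=10.0, bone_texture=5.0,
            noise_sigma=4.0,
        )
    return spec


def make_suite(
    n: int,
    seed: int = 0,
    difficulty: str = "easy",
    out_dir: str | Path | None = None,
) -> list[tuple[PhantomSpec, Radiograph, PhantomTruth, DetectionSet]]:
    """Generate ``n`` phantom / detections / truth triples.

    With ``out_dir`` set, each triple is written as
    ``phantom_XXX.png`` / ``.detections.json`` / ``.truth.json``.
    Deterministic: a fixed seed yields a byte-identical directory.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    out = []
    for i in range(n):
        sub_seed = (seed * 1000 + i) % (2 ** 31)
        rng = np.random.default_rng(sub_seed)
        spec = _spec_for(difficulty, sub_seed, rng)
        radiograph, truth = render_phantom(spec)
        dset = emit_detections(truth, jitter=2.0, seed=sub_seed + 1)
        out.append((spec, radiograph, truth, dset))
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            stem = out_dir / f"phantom_{i:03d}"
            write_image(radiograph, stem.with_suffix(".png"))
            write_detections(dset, f"{stem}.detections.json",
                             image=stem.with_suffix(".png").name)
            Path(f"{stem}.truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, sort_keys=True)
            )
    return out
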
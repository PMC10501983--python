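"""Shared fixtures and independent oracles.

The brute-force Hough accumulator here is deliberately written as
plain per-pixel/per-angle loops so it shares no code path with the
vectorized implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from periomark.config import PipelineConfig
from periomark.pipeline import analyze
from periomark.synthetic import PhantomSpec, emit_detections, render_phantom


# ---------------------------------------------------------------------------
# brute-force Hough oracle
# ---------------------------------------------------------------------------

def brute_force_accumulator(edge_map: np.ndarray):
    """Per-pixel, per-degree voting with explicit rounding."""
    h, w = edge_map.shape
    offset = int(math.ceil(math.hypot(h - 1, w - 1)))
    acc = np.zeros((2 * offset + 1, 180), dtype=int)
    for y in range(h):
        for x in range(w):
            if not edge_map[y, x]:
                continue
            for t in range(180):
                theta = math.radians(t)
                rho = round(x * math.cos(theta) + y * math.sin(theta))
                acc[rho + offset, t] += 1
    return acc, offset


def brute_force_peaks(acc: np.ndarray, offset: int, n_peaks: int, min_votes: int):
    """Local maxima (>= all existing 8 neighbors), sorted by
    (votes desc, rho asc, theta asc), truncated to n_peaks."""
    rows, cols = acc.shape
    found = []
    for r in range(rows):
        for t in range(cols):
            v = acc[r, t]
            if v < min_votes:
                continue
            is_max = True
            for dr in (-1, 0, 1):
                for dt in (-1, 0, 1):
                    if dr == 0 and dt == 0:
                        continue
                    rr, tt = r + dr, t + dt
                    if 0 <= rr < rows and 0 <= tt < cols and acc[rr, tt] > v:
                        is_max = False
            if is_max:
                found.append((-v, r - offset, t))
    found.sort()
    return [(float(rho), float(t), int(-nv)) for nv, rho, t in found[:n_peaks]]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def phantom():
    """Default two-implant lower-jaw phantom with 20% defects."""
    return render_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def analyzed(phantom):
    r, truth = phantom
    dset = emit_detections(truth, jitter=0.0, seed=5)
    report, art = analyze(r, dset)
    return r, truth, dset, report, art


def truth_lookup(truth):
    return {(e.implant, e.side): e for e in truth.edges}
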
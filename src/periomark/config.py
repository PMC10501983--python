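"""Pipeline configuration.

All tunable constants of the measurement procedure live here with their
defaults: gamma = 1.5 for the pre-Canny enhancement, 16 Hough peaks at
1 px x 1 deg resolution, 30 deg minimum slope, 10% bounding-box
expansion, 3x3 and 1x5 structuring elements, 10-px perpendicular scan
extent, 5-sample crown-entry run, detection score > 0.5, 30% minimum
crown overlap, 0.4 contrast threshold, 0.063 mm per vertical pixel and
alpha = 0.05 for the t tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the analysis pipeline, with defaults.

    Unknown keys in a YAML file or in ``replace`` are rejected so typos
    cannot silently fall back to defaults.
    """

    # detection gating
    score_min: float = 0.5            # detections kept iff score > score_min
    overlap_min: float = 0.3          # crown overlap fraction, strict >
    sigma_max: float = 98.0           # intensity std-dev mapping to sigma_norm = 1
    contrast_threshold: float = 0.4   # sigma_norm >= threshold -> high contrast
    auto_enhance: bool = True         # linear enhancement on low-contrast images

    # edge extraction
    gamma: float = 1.5
    canny_sigma: float = 1.6
    canny_high_pct: float = 97.0      # percentile of gradient magnitude
    canny_low_ratio: float = 0.5      # low = ratio * high
    roi_expand: float = 0.10          # +10% per dimension on screw boxes
    dilate_se: tuple[int, int] = (3, 3)

    # edge description
    hough_n_peaks: int = 16
    hough_min_votes: int = 15
    slope_min_deg: float = 30.0
    line_band: float = 2.0            # px perpendicular distance to a Hough line
    min_seg_len: float = 10.0         # px along-line extent of a kept segment
    max_gap: float = 3.0              # px gap bridged along a line
    min_group_px: int = 30
    group_dilate_se: tuple[int, int] = (1, 5)

    # critical points
    scan_start_offset: float = 3.0    # px away from the line before sampling
    scan_extent: int = 10             # px averaged per side (~2.5% of width 410)
    scan_persist: int = 3             # consecutive sub-mean samples for point 1
    scan_run_len: int = 5             # consecutive bright samples for point 2
    scan_min_drop: float = 20.0       # intensity levels below mean = "abrupt"
    run_factor: float = 1.15          # crown-entry threshold = factor * r_av
    verify_crown: bool = False

    # resorption / calibration
    calibration_mm_per_px: float = 0.063

    # evaluation
    alpha: float = 0.05
    n_batches: int = 10

    def replace(self, **kwargs) -> "PipelineConfig":
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        for key in ("dilate_se", "group_dilate_se"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls().replace(**data)


DEFAULT_CONFIG = PipelineConfig()
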
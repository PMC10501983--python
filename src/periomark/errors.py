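"""Exception hierarchy for the measurement pipeline.

Each pipeline stage raises its own error class so the CLI can map
failures to distinct exit codes (gating vs description vs scanning).
"""


class PeriomarkError(Exception):
    """Base class for all package errors."""


class ImageIOError(PeriomarkError):
    """Unreadable, empty or undecodable image / unwritable output."""


class FormatError(PeriomarkError):
    """Malformed detection or annotation file."""


class ParameterError(PeriomarkError):
    """Invalid parameter value (gamma <= 0, percentage out of range, ...)."""


class GatingError(PeriomarkError):
    """Image rejected before boundary analysis (no valid crown-screw pair,
    unknown jaw, mixed jaws)."""


class EnhancementError(PeriomarkError):
    """Linear contrast enhancement undefined (constant image)."""


class DescriptionError(PeriomarkError):
    """Edge description failed (empty edge map, no segments, no groups)."""


class FitError(PeriomarkError):
    """Polynomial fit is rank deficient or under-determined."""


class ScanError(PeriomarkError):
    """Perpendicular intensity scan left the image for most of its steps."""


class EvaluationError(PeriomarkError):
    """Evaluation statistics undefined (no overlap, degenerate sample, ...)."""
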
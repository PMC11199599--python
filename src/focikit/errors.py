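"""Exceptions raised by focikit contracts."""


class FocikitError(Exception):
    """Base class for all focikit errors."""


class PlacementError(FocikitError):
    """An object (nucleus or focus) could not be placed under the requested geometry."""


class GeometryError(FocikitError):
    """An ROI or stripe does not fit inside the available geometry."""


class DegenerateHistogramError(FocikitError):
    """Histogram has fewer than two occupied intensity levels; no threshold exists."""


class NoExpressingCellsError(DegenerateHistogramError):
    """Expression gating failed because the gating channel carries no contrast."""


class NormalizationError(FocikitError):
    """Baseline intensity is zero or negative; trace cannot be normalized."""


class AlignmentError(FocikitError):
    """Traces of unequal length cannot be aggregated frame-by-frame."""


class InsufficientDataError(FocikitError):
    """Too few post-damage frames to fit the recruitment model."""
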
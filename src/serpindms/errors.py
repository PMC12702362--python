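"""Exception hierarchy for the serpindms pipeline.

Every stage raises a subclass of :class:`SerpinDMSError`, so callers (and the
CLI) can abort with the stage name and offending input without catching bare
exceptions.
"""


class SerpinDMSError(Exception):
    """Base class for all serpindms errors."""


class ConfigurationError(SerpinDMSError):
    """Invalid simulation or run configuration."""


class DegenerateSelectionError(SerpinDMSError):
    """Selection step where every capture probability is zero."""


class NormalizationError(SerpinDMSError):
    """Size-factor estimation impossible (no variant positive in all samples)."""


class InputError(SerpinDMSError):
    """Malformed or inconsistent stage input (missing condition, disjoint keys...)."""


class QCError(SerpinDMSError):
    """Sample-level QC impossible (e.g. fewer than 3 samples for PCA)."""


class SmoothingError(SerpinDMSError):
    """Fewer positions with values than the smoothing window."""


class StratificationError(SerpinDMSError):
    """A stratum is empty or too small after joining tables."""


class ModelError(SerpinDMSError):
    """Mixed-model fit impossible (too few positions, singular design)."""


class RegressionError(SerpinDMSError):
    """Simple regression impossible (zero predictor variance, too few points)."""


class AnalysisError(SerpinDMSError):
    """Quadrant analysis impossible (an empty or undersized quadrant)."""


class DesignError(SerpinDMSError):
    """Two-way ANOVA design degenerate (constant or confounded factors)."""


class ParseError(SerpinDMSError):
    """Malformed table row; carries the 1-based row number when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ExportError(SerpinDMSError):
    """Table export impossible (duplicate variant keys...)."""
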
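"""Exception hierarchy.

All package errors derive from :class:`StainBenchError`, which itself
derives from :class:`ValueError` so callers can catch broadly.
"""


class StainBenchError(ValueError):
    """Base class for all stainbench errors."""


class InvalidImageError(StainBenchError):
    """Input is not a valid RGB raster (shape, dtype, range or alpha)."""


class DegenerateImageError(StainBenchError):
    """Image statistics are degenerate for the requested operation."""


class DegenerateReferenceError(StainBenchError):
    """Reference image cannot serve as a normalization target."""


class DegenerateSourceError(StainBenchError):
    """Source image cannot be normalized (e.g. zero channel variance)."""


class InsufficientTissueError(StainBenchError):
    """Too few tissue pixels remain after optical-density thresholding."""


class DegenerateStainError(StainBenchError):
    """Stain matrix is singular or the OD cloud is rank deficient."""


class BinningMismatchError(StainBenchError):
    """Histograms were built over different bin edges."""


class UndefinedCorrelationError(StainBenchError):
    """Pearson correlation is undefined (zero-variance histogram)."""


class ExtractorMismatchError(StainBenchError):
    """Feature clouds come from different extractors."""
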
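"""Typed exceptions raised across the pipeline.

Degenerate inputs (empty or full volumes, zero spectra, constant vectors)
raise rather than returning silent numbers, so a batch run fails loudly on
the exact stage and input that broke.
"""


class StromakitError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(StromakitError, ValueError):
    """A generator or config specification violates its invariants."""


class ConvergenceError(StromakitError, RuntimeError):
    """An iterative construction or fit did not converge within its budget."""


class DegenerateInputError(StromakitError, ValueError):
    """Input is constant/degenerate where variation is required."""


class EmptyStructureError(StromakitError, ValueError):
    """An operation needs a nonempty foreground (or background) phase."""


class TooSmallError(StromakitError, ValueError):
    """Grid is too small for the requested operation."""


class InsufficientScalesError(StromakitError, ValueError):
    """Fewer than three distinct box sizes available for the log-log fit."""


class AnisotropyFitError(StromakitError, RuntimeError):
    """The MIL ellipsoid fit is not positive definite."""


class WindowError(StromakitError, ValueError):
    """A spectral window is malformed or lies outside the axis range."""


class DegenerateSpectrumError(StromakitError, ValueError):
    """A spectrum has zero norm where normalization is required."""


class DegenerateClusteringError(StromakitError, ValueError):
    """Clustering with k > 1 requested on pixels with zero variance."""


class EmptyClusterError(StromakitError, ValueError):
    """A requested cluster label has no member pixels."""


class ParameterError(StromakitError, ValueError):
    """A numerical parameter (filter window, polynomial order, ...) is invalid."""


class FitError(StromakitError, RuntimeError):
    """Peak fitting failed after bounded restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MissingBandError(StromakitError, KeyError):
    """A required fitted band has no component within the matching tolerance."""

    def __init__(self, centroid_cm1: float):
        super().__init__(f"no fitted component within tolerance of {centroid_cm1:g} cm^-1")
        self.centroid_cm1 = centroid_cm1


class DegenerateGroupError(StromakitError, ValueError):
    """A comparison group is too small or has no variance."""


class InsufficientDataError(StromakitError, ValueError):
    """Not enough complete records for the requested analysis."""


class UndefinedCorrelationError(StromakitError, ValueError):
    """Correlation of a constant vector is undefined."""


class FormatError(StromakitError, ValueError):
    """A file does not conform to the expected on-disk format."""
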
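"""Exception hierarchy for shadecorr.

All errors derive from :class:`ShadingError` so callers can catch the
package's failures with a single except clause; the subclasses additionally
derive from the matching builtin (ValueError / RuntimeError / OSError) so
generic handling keeps working.
"""


class ShadingError(Exception):
    """Base class for all shadecorr errors."""


class DimensionError(ShadingError, ValueError):
    """Shapes of images, stacks or model fields are incompatible."""


class ModelValidityError(ShadingError, ValueError):
    """A shading model violates its invariants (e.g. non-positive flat-field)."""


class InputSizeError(ShadingError, ValueError):
    """Too few images (or frames) for the requested operation."""


class DegenerateInputError(ShadingError, ValueError):
    """Input carries no usable signal (all-zero stack, zero score denominator)."""


class DataError(ShadingError, ValueError):
    """Non-finite or otherwise unusable pixel data."""


class ConvergenceError(ShadingError, RuntimeError):
    """The solver diverged; carries diagnostics of the failed run."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
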
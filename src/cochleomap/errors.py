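"""Exception hierarchy for cochleomap.

Readers reject malformed input loudly; numerical routines raise rather than
return NaN so pipeline stages can never silently propagate bad geometry.
"""


class CochleoMapError(Exception):
    """Base class for all cochleomap errors."""


class InvalidInputError(CochleoMapError, ValueError):
    """Input violates a precondition (too few points, bad shapes, ...)."""


class DomainError(CochleoMapError, ValueError):
    """Numeric argument outside the mathematical domain of an operation."""


class InvalidLandmarkError(InvalidInputError):
    """An anatomical landmark is unusable (e.g. round-window center on the axis)."""


class FitFailureError(CochleoMapError, RuntimeError):
    """An iterative fit did not converge or the geometry is degenerate.

    ``last_params`` carries the final iterate when one exists.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class UndefinedAngleError(CochleoMapError):
    """One or more points lie on the modiolar axis; their angle is undefined.

    ``indices`` lists the offending point indices.
    """

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"angular depth undefined for on-axis points at indices {self.indices}"
        )


class AttachmentError(CochleoMapError):
    """A dendrite endpoint is too far from the centerline it should attach to."""


class GenerationError(CochleoMapError):
    """The synthetic-geometry solver could not satisfy the requested spec."""


class FormatError(CochleoMapError, ValueError):
    """A file does not conform to the expected on-disk format."""
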
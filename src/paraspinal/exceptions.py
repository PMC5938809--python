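"""Exception hierarchy shared across the package."""


class ParaspinalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ParaspinalError):
    """A file could not be parsed in any supported format."""


class AmbiguousVolumeError(FormatError):
    """A NIfTI file holds more than one axial slice; the caller must pick one."""


class GridMismatchError(ParaspinalError):
    """An image and mask (or two masks) do not share the same pixel grid."""


class EmptyRoiError(ParaspinalError):
    """A mask with no foreground pixels reached a quantification step."""


class SchemaError(ParaspinalError):
    """Records passed to a table writer do not share one schema."""


class DegenerateHistogramError(ParaspinalError):
    """All masked intensities are identical; no histogram can be built."""


class FitError(ParaspinalError):
    """The two-component histogram fit failed from every initialization.

    Carries the optimizer diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SizingError(ParaspinalError):
    """A requested phantom geometry cannot be realized on the grid."""


class MaskRegenerationError(ParaspinalError):
    """Boundary perturbation repeatedly emptied a simulated rater mask."""


class CompletenessError(ParaspinalError):
    """A subject-by-rater score grid has missing cells."""


class PairingError(ParaspinalError):
    """Method comparison found subjects without both ROI methods."""

    def __init__(self, message: str, subjects: list | None = None):
        super().__init__(message)
        self.subjects = subjects or []
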
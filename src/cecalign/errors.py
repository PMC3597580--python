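"""Exception hierarchy for cecalign."""


class CecAlignError(Exception):
    """Base class for all cecalign errors."""


class InvalidParameterError(CecAlignError, ValueError):
    """A configuration or operation parameter violates its constraints."""


class InvalidInputError(CecAlignError, ValueError):
    """An input object (image, point set) is unusable for the operation."""


class InvalidTransformError(CecAlignError, ValueError):
    """The affine transform is singular or otherwise unusable."""


class DegenerateFitError(CecAlignError, ValueError):
    """Too few or collinear correspondences for an affine regression fit."""


class OverlapUnreachableError(InvalidParameterError):
    """The requested overlap fraction cannot be realized for the given transform."""
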
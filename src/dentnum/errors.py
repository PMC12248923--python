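"""Exception and warning types shared across the package."""


class DentnumError(Exception):
    """Base class for all package-specific errors."""


class InvalidImageError(DentnumError):
    """Raster does not satisfy the operation's channel/shape contract."""


class InvalidParameterError(DentnumError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidStateError(DentnumError):
    """Operations were applied in an unsupported order (e.g. pad before resize)."""


class LabelFormatError(DentnumError):
    """A YOLO label line could not be parsed."""


class LabelValidationError(DentnumError):
    """A parsed label value is outside its normalized range."""


class DegenerateArchError(DentnumError):
    """The layout does not contain two separable dental arches."""

    def __init__(self, message: str, jaw_found: str | None = None):
        super().__init__(message)
        self.jaw_found = jaw_found


class QuadrantOverflowError(DentnumError):
    """Inferred tooth positions would exceed the quadrant capacity."""


class WrongModalityError(DentnumError):
    """The numbering routine does not apply to this image modality."""


class GenerationError(DentnumError):
    """A synthetic layout cannot be realized inside the requested frame."""


class SchemaError(DentnumError):
    """Two presence tables do not cover the same code set."""


class ConfigurationError(DentnumError):
    """Pipeline configuration is incomplete or inconsistent."""


class DentnumWarning(UserWarning):
    """Base class for package warnings."""


class DegenerateInputWarning(DentnumWarning):
    """A degenerate input was handled by a documented fallback."""


class OutOfContentWarning(DentnumWarning):
    """A mapped point lies inside the letterbox padding, not the image content."""


class ZeroDenominatorWarning(DentnumWarning):
    """A metric denominator was zero; the metric is reported as 0 by convention."""
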
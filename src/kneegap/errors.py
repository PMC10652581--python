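"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`KneegapError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class KneegapError(Exception):
    """Base class for all kneegap errors."""


class ParameterError(KneegapError, ValueError):
    """A scalar argument is out of its admissible range."""


class GeometryError(KneegapError):
    """A geometric construction cannot be carried out on the given input."""


class ContourError(GeometryError):
    """A bone contour is open, self-intersecting or otherwise unusable."""


class AnnotationError(KneegapError):
    """A radiograph annotation lacks a required element or holds a bad one."""


class CalibrationError(KneegapError):
    """Magnification calibration misuse (e.g. calibrating twice)."""


class RegistrationError(KneegapError):
    """Pre-/post-operative cut-line overlay cannot be registered."""


class CollinearityError(KneegapError):
    """A design matrix is rank deficient.

    ``term`` names the offending column when it can be identified.
    """

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


class ValidationError(KneegapError):
    """Itemised schema validation failure; ``items`` lists every problem."""

    def __init__(self, items: list[str]):
        super().__init__("; ".join(items))
        self.items = list(items)


class GenerationError(KneegapError):
    """The synthetic-knee generator produced an unusable contour."""
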
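"""Exception hierarchy.

``TriRGBError`` is the base; ``UsageError`` maps to CLI exit code 1,
``DataError`` (and subclasses) to exit code 2.
"""


class TriRGBError(Exception):
    """Base class for all trirgb errors."""


class UsageError(TriRGBError):
    """Invalid parameters or conflicting options."""


class DataError(TriRGBError):
    """Invalid or inconsistent input data."""


class EmptyFieldError(DataError):
    """A field with no valid (unmasked) cells."""


class DegenerateRangeError(DataError):
    """Derived c_min equals c_max; normalization is undefined."""


class CoRegistrationError(DataError):
    """Fields meant to share a grid have mismatched axes or shapes."""


class TriangulationError(DataError):
    """Scattered samples cannot be triangulated (too few / collinear)."""
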
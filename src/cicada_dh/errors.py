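"""Exception hierarchy for the dorsal-horn imaging pipeline.

Every error raised on bad input or a failed stage derives from
:class:`CicadaError` so callers can catch pipeline problems as one family
while letting programming errors propagate.
"""


class CicadaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CicadaError, ValueError):
    """A file does not conform to its on-disk format (ragged rows, bad header)."""


class ParseError(FormatError):
    """A value inside an otherwise well-formed file could not be parsed."""


class SchemaError(CicadaError, ValueError):
    """A structured record violates its schema (unknown family, stray grid site)."""


class ConfigError(CicadaError, ValueError):
    """A configuration value is out of its legal range."""


class NumericError(CicadaError, ValueError):
    """A numeric precondition failed (non-positive baseline, bad median)."""


class WindowOutOfRange(CicadaError, ValueError):
    """A response/noise window does not fit inside the recording."""


class AssignmentError(CicadaError, ValueError):
    """Family-level response assignment was requested with no trials."""


class CalibrationError(CicadaError, ValueError):
    """Threshold calibration is impossible (single-class annotations)."""


class ExcludedCell(CicadaError, ValueError):
    """The cell must be excluded from this analysis (e.g. no responses at all)."""


class SelectionError(CicadaError, ValueError):
    """Model selection (choice of k) failed on degenerate input."""


class SurfaceError(CicadaError, ValueError):
    """No usable surface estimate could be extracted from the structural volume."""


class AlignmentError(CicadaError, ValueError):
    """Pre/post blocks (or tables) do not cover the same cells."""
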
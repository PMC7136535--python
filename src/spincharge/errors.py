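"""Exception hierarchy.

Errors are grouped so the command-line layer can map them onto distinct
exit codes: configuration problems, data/format problems, and I/O problems.
"""


class SpinChargeError(Exception):
    """Base class for all package errors."""


class ConfigError(SpinChargeError):
    """Invalid configuration value (bad fraction, unknown scheme, ...)."""


class DataError(SpinChargeError):
    """Invalid data content (NaN responses, misaligned frames, ...)."""


class ParseError(DataError):
    """Malformed geometry file; message names the offending line."""


class FormatError(DataError):
    """Malformed charge table or report file."""


class AlignmentError(DataError):
    """Structures and charge tables do not cover the same frames/atoms."""


class DegenerateGeometryError(DataError):
    """Coincident or collinear atoms where a descriptor is undefined."""


class LayoutError(DataError):
    """Structure composition incompatible with a descriptor layout/model."""


class ModelLoadError(SpinChargeError):
    """Model archive unreadable, truncated, or of an unknown version."""


class UndefinedCorrelationError(DataError):
    """Pearson correlation requested on zero-variance input."""
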
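"""Exception hierarchy used across the package."""


class GlenoidOAMError(Exception):
    """Base class for all package errors."""


class ValidationError(GlenoidOAMError, ValueError):
    """Invalid parameter or record; the message names the offending field."""


class SizingError(GlenoidOAMError, ValueError):
    """Requested phantom geometry does not fit in the voxel grid."""


class FormatError(GlenoidOAMError, IOError):
    """Unreadable or unsupported image / landmark file."""


class DegenerateGeometryError(GlenoidOAMError, ValueError):
    """Collinear or coincident landmarks make a construction ill-defined."""


class ExtractionError(GlenoidOAMError, RuntimeError):
    """No articular surface could be extracted from the bone mask."""
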
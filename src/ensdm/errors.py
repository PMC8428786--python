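"""Exception hierarchy.

Two top-level families map onto the CLI exit codes: :class:`ValidationError`
(bad configuration or arguments, exit code 2) and :class:`DataError`
(inconsistent or unusable input data, exit code 3).
"""


class EnsdmError(Exception):
    """Base class for all package errors."""


class ValidationError(EnsdmError, ValueError):
    """Invalid configuration, parameters or arguments."""


class DataError(EnsdmError, ValueError):
    """Input data is inconsistent or unusable."""


class GeometryError(DataError):
    """Raster grids do not share the same geometry."""


class NamingError(ValidationError):
    """Duplicate or missing layer / variable names."""


class ExtentError(DataError):
    """Points fall outside the raster extent."""


class DegenerateDataError(DataError):
    """Data is degenerate for the requested fit (e.g. constant column)."""


class GateError(DataError):
    """No candidate model survived the performance gate."""
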
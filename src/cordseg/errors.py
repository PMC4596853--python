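"""Exception types shared across the package."""


class CordSegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CordSegError, ValueError):
    """Raised for malformed or unsupported on-disk inputs."""


class GeometryError(CordSegError, ValueError):
    """Raised when a geometric precondition is violated (cord exits the
    grid, point outside the spline's capture region, reversed region, ...)."""
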
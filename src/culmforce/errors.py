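"""Exception hierarchy shared across the pipeline stages."""


class CulmforceError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CulmforceError, ValueError):
    """Invalid user-supplied parameter (radii ordering, step sizes, ...)."""


class GeometryError(CulmforceError):
    """Inconsistent stem geometry, e.g. overlapping bundles."""


class SpatialError(CulmforceError):
    """Object does not fit into the requested spatial domain."""


class DegenerateError(CulmforceError):
    """Input degenerate for the requested computation (zero variance, ...)."""


class AlignmentError(CulmforceError):
    """Spectral grids cannot be brought onto a common axis."""


class LibraryError(CulmforceError):
    """Component reference library unusable (rank deficient, empty, ...)."""


class RangeError(CulmforceError):
    """Requested spectral range not covered by the data."""


class ValidationError(CulmforceError):
    """Tabular input violates its schema (unknown codes, bad columns)."""
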
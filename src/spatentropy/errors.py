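"""Exception hierarchy with stable categories for CLI exit codes."""


class SpatEntropyError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(SpatEntropyError):
    """Malformed input file (CSV, WKT, GeoJSON, ASCII grid)."""

    exit_code = 3


class GeometryError(SpatEntropyError):
    """Invalid geometry (self-intersecting polygon, degenerate window)."""

    exit_code = 4


class ContainmentError(SpatEntropyError):
    """Points fall outside the observation window."""

    exit_code = 4


class CoverageError(SpatEntropyError):
    """A point could not be assigned to any sub-area of a partition."""

    exit_code = 4


class ParameterError(SpatEntropyError):
    """Invalid parameter value (neigh >= G, k too large, d <= 0, ...)."""

    exit_code = 5


class EmptyTableError(SpatEntropyError):
    """No co-occurrences found under the given rule.

    Carries the minimum interpoint distance so the user can pick a
    feasible threshold.
    """

    exit_code = 6

    def __init__(self, message: str, min_distance: float | None = None):
        super().__init__(message)
        self.min_distance = min_distance
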
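"""Exception hierarchy shared across pipeline stages.

Exit-code contract for the CLI: schema problems -> 2, geometry problems -> 3,
convergence failures (strict mode) -> 4.
"""


class StonewortError(Exception):
    """Base class for package errors."""

    exit_code = 1


class SchemaError(StonewortError):
    """Malformed or inconsistent input tables/configuration."""

    exit_code = 2


class ConfigurationError(SchemaError):
    """A required configuration element is missing or contradictory."""


class GeometryError(StonewortError):
    """Invalid geometric input (point on land, degenerate polygon, ...)."""

    exit_code = 3


class NoPathError(GeometryError):
    """No water-constrained path exists between two points."""


class ConvergenceError(StonewortError):
    """MCMC convergence diagnostics exceeded the configured thresholds."""

    exit_code = 4
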
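"""Exception hierarchy for e-nose data handling and analysis."""


class EnoseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EnoseError, ValueError):
    """A CSV file does not conform to the declared dialect (missing columns etc.)."""


class DialectError(EnoseError, ValueError):
    """The file parses but violates a dialect assumption (e.g. non-constant time step)."""


class InsufficientDataError(EnoseError, ValueError):
    """Too few samples / time points / classes for the requested operation."""


class ShapeError(EnoseError, ValueError):
    """Inconsistent array dimensions between inputs."""


class SingularityError(EnoseError, ValueError):
    """A matrix that must be inverted (or whose determinant is needed) is singular."""


class ConfigError(EnoseError, ValueError):
    """An invalid pipeline or generator configuration."""
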
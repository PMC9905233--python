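"""Exception hierarchy shared across the package."""


class CohesimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CohesimError, ValueError):
    """A configuration object failed validation; the message names the field."""


class TrajectoryError(CohesimError, ValueError):
    """A movement log is internally inconsistent (teleport, bad ordering, off-board cell)."""


class SchemaError(CohesimError, ValueError):
    """A CSV/JSON input does not match the documented dialect."""


class EmptyInputError(CohesimError, ValueError):
    """An operation that requires data received an empty input."""
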
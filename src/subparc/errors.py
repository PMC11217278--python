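"""Exception hierarchy mapped onto CLI exit codes."""


class SubparcError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(SubparcError):
    """Invalid configuration or specification (exit code 2)."""

    exit_code = 2


class DataError(SubparcError):
    """Malformed or inconsistent input data (exit code 3)."""

    exit_code = 3


class GeometryError(DataError):
    """Geometric precondition violated (subclass of data errors)."""


class StatsPreconditionError(SubparcError):
    """A statistical routine's preconditions are not met (exit code 4)."""

    exit_code = 4
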
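"""Exception hierarchy with CLI exit codes.

Exit code convention: 2 = configuration error, 3 = data error,
4 = stage/pipeline error.  ``MolscreenError`` is the common base so
callers can catch everything from this package in one clause.
"""


class MolscreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(MolscreenError):
    """Invalid configuration value or combination."""

    exit_code = 2


class DataError(MolscreenError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class SchemaError(DataError):
    """Column set does not match what an operation requires."""

    exit_code = 3


class MetricError(DataError):
    """A metric is undefined for the given input (e.g. single-class AUC)."""

    exit_code = 3


class StageError(MolscreenError):
    """A pipeline stage failed; carries the stage name."""

    exit_code = 4

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
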
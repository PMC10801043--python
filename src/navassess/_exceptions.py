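"""Exception hierarchy shared across the package."""


class NavassessError(Exception):
    """Base class for all package-specific errors."""


class InputError(NavassessError, ValueError):
    """Invalid argument values (wrong item counts, out-of-range responses, ...)."""


class ConfigError(NavassessError, ValueError):
    """Invalid cohort or pipeline configuration, raised before any generation."""


class ParseError(NavassessError):
    """A malformed row in a session log file, located by file, line and column."""

    def __init__(self, path, message, line=None, column=None):
        self.path = str(path)
        self.line = line
        self.column = column
        loc = self.path
        if line is not None:
            loc += f":{line}"
        if column is not None:
            loc += f" (column {column!r})"
        super().__init__(f"{loc}: {message}")


class SessionValidationError(NavassessError):
    """A structural invariant violated in a session log (e.g. duplicate trials)."""


class DegenerateVarianceError(InputError):
    """Paired differences have zero variance; the t statistic is undefined."""


class ModelError(NavassessError):
    """A mixed-model fit cannot be carried out (empty cells, too few levels)."""


class AdapterError(NavassessError):
    """An external data deposit could not be mapped onto the session model."""
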
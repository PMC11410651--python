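"""Exception types shared across the package."""


class EpicenmapError(Exception):
    """Base class for package errors."""


class ConfigurationError(EpicenmapError, ValueError):
    """A scenario or genome configuration is internally inconsistent."""


class InputError(EpicenmapError, ValueError):
    """An input object violates a documented precondition."""


class ParseError(EpicenmapError, ValueError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ContextBoundaryError(EpicenmapError, ValueError):
    """A cytosine is too close to the sequence end to assign a context.

    Callers scanning whole chromosomes skip such sites.
    """
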
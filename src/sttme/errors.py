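"""Exception hierarchy shared across the package."""


class SttmeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SttmeError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(SttmeError, ValueError):
    """An input file or table violates its format contract."""


class EmptyResultError(SttmeError):
    """An operation removed or excluded everything; carries a report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ConfigError(SttmeError, ValueError):
    """Pipeline configuration invalid; raised before any stage runs."""
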
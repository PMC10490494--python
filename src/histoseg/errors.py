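"""Exception hierarchy shared across the package."""


class HistosegError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HistosegError, ValueError):
    """A function argument violates its documented precondition."""


class ValidationError(HistosegError, ValueError):
    """Data failed an internal consistency check (shapes, value ranges, pairing)."""


class InvalidSpecError(HistosegError, ValueError):
    """A network specification is internally inconsistent."""


class DegenerateInputError(HistosegError, ValueError):
    """Input admits no meaningful answer (e.g. clustering identical points)."""


class StateError(HistosegError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class FormatError(HistosegError, ValueError):
    """A file exists but cannot be decoded as a supported image format."""
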
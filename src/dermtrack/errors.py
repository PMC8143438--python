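"""Exception hierarchy shared across the package."""


class DermtrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DermtrackError):
    """A file does not conform to the expected table/image dialect."""


class ValidationError(DermtrackError):
    """Structurally parseable data violates a domain invariant."""


class ConfigError(DermtrackError):
    """A run configuration is invalid."""


class ComputationError(DermtrackError):
    """A quantity is undefined for the given input (e.g. zero duration)."""
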
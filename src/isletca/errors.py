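"""Exception hierarchy shared across the package."""


class IsletError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(IsletError):
    """A CSV/JSON input does not have the expected layout or contains
    unparseable cells."""


class ConfigError(IsletError):
    """An experiment timeline or run configuration fails validation."""


class DegenerateTraceError(IsletError):
    """A trace cannot be analysed (constant signal, non-positive baseline)."""
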
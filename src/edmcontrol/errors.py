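"""Exception hierarchy.

All errors raised deliberately by this package derive from
:class:`EdmControlError` so callers (and the CLI) can distinguish
configuration mistakes from genuine bugs.
"""


class EdmControlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EdmControlError):
    """Invalid configuration: unknown column, bad split, unknown scenario ..."""


class FormatError(EdmControlError):
    """A file did not conform to the expected on-disk format."""


class EmptyLibraryError(EdmControlError):
    """An embedding produced no valid state vectors."""


class InsufficientLibraryError(EdmControlError):
    """Not enough library rows (with defined futures) for the request."""


class ParameterError(EdmControlError):
    """A numeric parameter is out of its admissible range."""
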
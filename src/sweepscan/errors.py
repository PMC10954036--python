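"""Exception hierarchy.

``ValidationError`` means the caller handed us an impossible configuration;
``DataError`` means the inputs themselves are malformed or insufficient.
The CLI maps them to exit codes 2 and 3 respectively.
"""


class SweepscanError(Exception):
    """Base class for all package errors."""


class ValidationError(SweepscanError):
    """Invalid configuration or parameters."""


class DataError(SweepscanError):
    """Malformed or insufficient input data."""
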
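"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input data; ``UsageError``
covers bad parameterisation.  The CLI maps these to distinct exit codes.
"""


class PaleomtError(Exception):
    """Base class for all package errors."""


class DataError(PaleomtError):
    """Malformed, inconsistent, or unsupported input data."""


class UsageError(PaleomtError):
    """Invalid parameters or parameter combinations."""
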
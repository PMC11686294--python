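"""Exception hierarchy.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3; everything else is a bug.
"""


class TfbscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TfbscapeError):
    """Invalid parameters, missing weights, malformed configs."""


class DataError(TfbscapeError):
    """Malformed or inconsistent input data."""


class UndefinedScoreError(DataError):
    """A score was requested for a genotype with no reads."""
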
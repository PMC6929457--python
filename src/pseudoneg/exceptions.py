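"""Exception hierarchy.

All errors raised by this package derive from :class:`PseudonegError` so
callers can catch everything from one base; the subclasses separate bad
user configuration from bad data and from internal consistency failures.
"""


class PseudonegError(Exception):
    """Base class for all errors raised by pseudoneg."""


class ConfigError(PseudonegError, ValueError):
    """An option or parameter combination is invalid."""


class DataValidationError(PseudonegError, ValueError):
    """Input data violates the dataset contract (non-finite values,
    non-binary labels, shape mismatches). Carries row/column coordinates
    where available."""


class DegenerateSampleError(DataValidationError):
    """One or more sample rows have zero variance, making the Pearson
    correlation undefined for them."""

    def __init__(self, rows, message=None):
        self.rows = list(rows)
        super().__init__(
            message
            or f"zero-variance sample rows make Pearson correlation undefined: {self.rows}"
        )


class IntegrityError(PseudonegError, ValueError):
    """Objects passed together do not belong together (e.g. a selection
    result applied to a different dataset than it was computed on)."""
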
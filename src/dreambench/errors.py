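"""Exception hierarchy.

All package errors derive from :class:`DreamBenchError`; validation errors
additionally derive from :class:`ValueError` so generic numeric code can
catch them without importing this module.
"""


class DreamBenchError(Exception):
    """Base class for all package errors."""


class ValidationError(DreamBenchError, ValueError):
    """An in-memory object or argument violates a stated invariant."""


class FormatError(DreamBenchError):
    """A submission or gold-standard file failed to parse or validate.

    Carries enough position information (line number, block, column) in the
    message to locate the offending record.
    """


class ScoringError(DreamBenchError):
    """A scoring procedure could not be completed on otherwise valid input."""


class UnknownChallengeError(DreamBenchError):
    """A challenge nickname is not present in the registry."""


class UsageError(DreamBenchError):
    """The caller invoked a challenge incorrectly (e.g. missing sub-challenge)."""
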
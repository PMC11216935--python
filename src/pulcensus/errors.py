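"""Exception hierarchy.

Every error raised on bad input derives from :class:`PulcensusError`, so
callers (and the CLI) can catch one type and exit non-zero with a message.
"""


class PulcensusError(Exception):
    """Base class for all package errors."""


class FormatError(PulcensusError):
    """A file or text blob does not conform to its declared format."""


class DuplicateIdError(FormatError):
    """Duplicate gene identifiers in a single table."""

    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates)
        super().__init__(f"duplicate gene_id values: {', '.join(self.duplicates)}")


class IntegrityError(PulcensusError):
    """Internally inconsistent record (e.g. declared length != sequence length)."""


class CoordinateError(PulcensusError):
    """A domain hit is missing the coordinates an operation requires."""


class InsufficientDataError(PulcensusError):
    """Too few observations to infer anything."""


class LookupError_(PulcensusError):
    """An identifier does not resolve within the dataset."""


class StateError(PulcensusError):
    """An operation was called on an object in the wrong state."""


class ConfigError(PulcensusError):
    """An infeasible or contradictory configuration."""
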
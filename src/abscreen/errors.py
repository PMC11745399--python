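"""Exception taxonomy for the screening pipeline.

Backends raise :class:`RateLimitError` for throttling failures (the only
retriable class) and :class:`BackendError` for everything else; the judge
maps unparseable responses to :class:`VerdictParseError`.
"""

from __future__ import annotations


class AbscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AbscreenError):
    """A config object or call is internally inconsistent."""


class MissingColumnError(ConfigurationError):
    """A mapped column is absent from the input table."""

    def __init__(self, column: str) -> None:
        self.column = column
        super().__init__(f"mapped column not found in input table: {column!r}")


class LabelParseError(AbscreenError):
    """A screening label could not be interpreted."""


class InconsistentLabelsError(AbscreenError):
    """screening2 = included on a record with screening1 = excluded."""


class EmptyDatasetError(AbscreenError):
    """Preprocessing removed every record."""


class RecordNotFoundError(KeyError, AbscreenError):
    """An exact-ID lookup missed; never silently falls back to similarity."""


class EmbeddingError(AbscreenError):
    """An embedding batch failed; carries the affected record ids (retriable)."""

    def __init__(self, message: str, record_ids: list[str]) -> None:
        self.record_ids = list(record_ids)
        super().__init__(message)


class VerdictParseError(AbscreenError):
    """No recoverable JSON verdict object in a judge response."""


class BackendError(AbscreenError):
    """Non-retriable judge backend failure."""


class RateLimitError(BackendError):
    """Retriable throttling failure from a judge backend."""


class CheckpointError(AbscreenError):
    """Checkpoint file is corrupt; resuming is refused."""


class AlignmentError(AbscreenError):
    """Decision and truth vectors do not describe the same records."""


class InsufficientClassError(AbscreenError):
    """A class has fewer than two members; stratified CV is impossible."""


class AccountingError(AbscreenError):
    """Workload bookkeeping violated (e.g. correct > original total)."""
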
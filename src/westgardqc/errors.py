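"""Exception hierarchy for QC data handling and analysis contracts."""


class QCDataError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(QCDataError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class RecordError(QCDataError):
    """A single record is malformed or violates a field invariant."""


class IntegrityError(QCDataError):
    """Duplicate or conflicting records within one dataset."""


class ConfigError(QCDataError):
    """Inconsistent study configuration (dangling references, overlaps)."""


class ContractError(QCDataError):
    """An operation was called with arguments violating its precondition."""


class CoverageError(QCDataError):
    """Data falls outside every configured phase, or an analyte is missing."""


class InsufficientDataError(QCDataError):
    """Too few observations to compute the requested statistic."""


class DomainError(QCDataError):
    """A numeric argument is outside the mathematical domain of a formula."""
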
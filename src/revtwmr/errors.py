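"""Exception hierarchy for revtwmr.

Every error raised on a contract violation derives from :class:`RevtwmrError`
so callers can catch package failures with a single except clause while still
letting programming errors (TypeError etc.) propagate.
"""

from __future__ import annotations


class RevtwmrError(Exception):
    """Base class for all revtwmr errors."""


class ConfigurationError(RevtwmrError):
    """A column map, config file or argument is malformed or missing."""


class EmptyInputError(RevtwmrError):
    """An input table contains no usable data rows."""


class DuplicateRecordError(RevtwmrError):
    """Keyed-uniqueness violation in an input table."""

    def __init__(self, message: str, duplicates: list | None = None):
        super().__init__(message)
        self.duplicates = duplicates or []


class NoInstrumentsError(RevtwmrError):
    """No instruments survive harmonization / selection filters.

    ``removal_counts`` records how many SNPs each filter removed so the
    caller can report why a gene could not be estimated.
    """

    def __init__(self, message: str, removal_counts: dict | None = None):
        super().__init__(message)
        self.removal_counts = removal_counts or {}


class DegenerateInstrumentsError(RevtwmrError):
    """All exposure effects are zero; the IVW ratio is undefined."""


class DegenerateInputError(RevtwmrError):
    """A vector is constant where variation is required (e.g. INT input)."""


class NoiseDominatesError(RevtwmrError):
    """An errors-in-variables attenuation factor is <= 0; the dilution
    adjustment is undefined because estimation noise exceeds the signal."""


class CollinearCovariatesError(RevtwmrError):
    """Covariate matrix is rank deficient after adding the intercept."""

    def __init__(self, message: str, columns: list | None = None):
        super().__init__(message)
        self.columns = columns or []
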
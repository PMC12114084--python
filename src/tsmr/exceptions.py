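"""Exception hierarchy for the MR pipeline.

Statistical insufficiency inside a batch run is reported as data
(``PairResult.not_analyzable``), never raised; these exceptions cover
misconfiguration and direct misuse of the low-level API.
"""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """Invalid configuration: missing columns, bad scenario parameters, empty plans."""


class EmptyInputError(TsmrError):
    """An input table contained no valid rows."""


class DuplicateSNPError(TsmrError):
    """A trait table contained a duplicated variant identifier."""

    def __init__(self, snp_id: str):
        self.snp_id = snp_id
        super().__init__(f"duplicated snp_id within one trait table: {snp_id!r}")


class MissingEAFError(TsmrError):
    """An operation that requires the effect-allele frequency met a record without one."""


class NoOverlapError(TsmrError):
    """Exposure and outcome tables share no variants."""


class ZeroInstrumentError(TsmrError):
    """No instruments survived a selection or filtering stage."""


class InsufficientInstrumentsError(TsmrError):
    """Fewer instruments than the method's minimum."""


class DomainError(TsmrError):
    """Argument outside a formula's mathematical domain (e.g. R-squared >= 1)."""
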
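"""Exception hierarchy shared across the package."""


class PdzScanError(Exception):
    """Base class for all package errors."""


class DataValidationError(PdzScanError):
    """Malformed or inconsistent input data (exit code 2 on the CLI)."""


class RaggedAlignmentError(DataValidationError):
    """FASTA records of unequal length where an alignment was expected."""
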
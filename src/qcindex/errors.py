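"""Exception types shared across the package."""


class QCIndexError(Exception):
    """Base class for all package errors."""


class ContractError(QCIndexError, ValueError):
    """A documented precondition of an operation was violated by the caller."""


class FormatError(QCIndexError, ValueError):
    """An input file does not conform to the expected tabular dialect."""
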
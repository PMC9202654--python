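"""Exception hierarchy shared across the package."""


class BehaviorMinerError(Exception):
    """Base class for all package errors."""


class CodebookError(BehaviorMinerError):
    """A column, question or answer does not match the codebook."""


class ValidationError(BehaviorMinerError):
    """Input data violates a precondition (bad cell value, empty table, ...)."""


class ConfigurationError(BehaviorMinerError):
    """A configuration object is internally inconsistent or out of range."""


class SpecificationError(BehaviorMinerError):
    """A synthetic-data specification is contradictory (e.g. planted items
    assigning two different answers to the same question)."""
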
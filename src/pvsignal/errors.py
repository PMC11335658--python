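"""Exception types shared across the package."""


class PvSignalError(Exception):
    """Base class for package errors."""


class SchemaError(PvSignalError):
    """An input table is missing a mandatory column or uses an unknown layout."""


class ConfigurationError(PvSignalError):
    """A run or generator configuration is invalid."""


class DataError(PvSignalError):
    """An input file violates a data contract (e.g. conflicting PT->SOC rows)."""


class ConsistencyError(PvSignalError):
    """An internal invariant was violated (e.g. a negative contingency cell)."""
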
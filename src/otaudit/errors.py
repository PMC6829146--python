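"""Exception hierarchy for the off-target audit pipeline."""


class OtauditError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(OtauditError, ValueError):
    """An argument violates a documented precondition."""


class DataIntegrityError(OtauditError):
    """Input data contradicts itself (e.g. REF allele does not match the genome)."""


class UndefinedVAFError(OtauditError):
    """Variant allele fraction requested for a record with zero allele depth."""


class DegenerateDataError(OtauditError):
    """A statistic is undefined for the given data (e.g. all values tied)."""


class ConfigError(OtauditError):
    """A run configuration is incomplete or inconsistent."""
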
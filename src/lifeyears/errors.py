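"""Exception hierarchy for life-table parsing and validation."""


class LifeYearsError(Exception):
    """Base class for all package errors."""


class FormatError(LifeYearsError):
    """A file is missing mandatory columns or cannot be parsed."""


class StructureError(LifeYearsError):
    """The age grid is not a contiguous run of integers starting at 0."""


class ValidityError(LifeYearsError):
    """Column values violate life-table constraints (negative counts,
    non-monotone survivorship, all-zero cohort, ...)."""


class ConfigError(LifeYearsError):
    """Inconsistent or out-of-domain configuration."""


class FitError(LifeYearsError):
    """A model fit could not be carried out or its result cannot be used."""
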
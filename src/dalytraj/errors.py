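"""Exception types shared across the package."""


class DalytrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DalytrajError, ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class DataError(DalytrajError, ValueError):
    """Input data violate a contract (identifies the offending rows/fields)."""


class CohortRangeError(DataError):
    """A birth year falls outside the configured cohort span."""


class ModelSpecError(ConfigurationError):
    """A model specification references terms absent from the data."""
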
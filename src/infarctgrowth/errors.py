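"""Exception types shared across the package."""


class InfarctGrowthError(Exception):
    """Base class for all package-specific errors."""


class InvalidTimeError(InfarctGrowthError, ValueError):
    """Scan times violate the required ordering or positivity."""


class InvalidParameterError(InfarctGrowthError, ValueError):
    """A model parameter is outside its valid domain (e.g. non-positive width)."""


class LogDomainError(InfarctGrowthError, ValueError):
    """The exponential growth model requires a positive inter-scan slope."""


class OutOfSupportError(InfarctGrowthError, ValueError):
    """Query point lies so far outside the training range that no rule fires."""


class UnderdeterminedError(InfarctGrowthError, ValueError):
    """Too few training pairs to determine the consequent coefficients."""


class InsufficientDataError(InfarctGrowthError, ValueError):
    """Cohort too small for the requested split or fit."""


class UndefinedStatisticError(InfarctGrowthError, ValueError):
    """Statistic undefined for this input (constant sample, short vector)."""


class ConfigError(InfarctGrowthError, ValueError):
    """Infeasible or inconsistent configuration values."""
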
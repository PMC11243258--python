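"""Exception hierarchy shared across the package."""


class SteatoscoreError(Exception):
    """Base class for package errors."""


class DomainError(SteatoscoreError, ValueError):
    """An input is outside the mathematical domain of an operation
    (e.g. a non-positive analyte fed to a logarithm)."""


class ValidityError(SteatoscoreError, ValueError):
    """An input violates a validity condition of a clinical formula
    (e.g. triglycerides above the Friedewald ceiling)."""


class DegenerateOutcomeError(SteatoscoreError, ValueError):
    """A binary outcome vector contains a single class, so ROC
    quantities are undefined."""


class UndefinedStatisticError(SteatoscoreError, ValueError):
    """A statistic is undefined for the given data (zero variance,
    single-class marginal, ...)."""


class ConfigurationError(SteatoscoreError, ValueError):
    """A configuration table or option does not cover the input."""


class InputError(SteatoscoreError, ValueError):
    """A cohort input file cannot be used (unreadable, empty, or
    rejected at a rate suggesting column mis-mapping)."""
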
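"""Exception and warning types shared across the pipeline."""


class SalicoreError(Exception):
    """Base class for all package errors."""


class MissingTimepointError(SalicoreError):
    """A required measurement day is absent from a phenotype record."""


class InvalidMassError(SalicoreError):
    """Dry mass exceeds fresh mass, or a mass is outside its domain."""


class DivisionDomainError(SalicoreError):
    """A ratio was requested with a non-positive denominator."""


class SchemaError(SalicoreError):
    """A tabular input does not match the expected column schema."""


class DegenerateDesignError(SalicoreError):
    """A regression design carries no usable variation."""


class NoSolutionError(SalicoreError):
    """An inverse-prediction equation has no finite solution."""


class RecommendationUndefinedError(SalicoreError):
    """No dose-response fit yields a finite target concentration."""


class UndefinedStatisticError(SalicoreError):
    """A statistic was requested on an empty or degenerate input."""


class CoreSizeError(SalicoreError):
    """Requested core size is infeasible for the collection."""


class CombinatorialBudgetError(SalicoreError):
    """Exhaustive enumeration would exceed the allowed subset count."""


class SyntheticSpecError(SalicoreError):
    """A synthetic-data specification is internally inconsistent."""


class PipelineConfigError(SalicoreError):
    """A pipeline configuration fails validation before any stage runs."""


class DegenerateTraitWarning(UserWarning):
    """A trait column has zero range and was handled degenerately."""


class ExclusionWarning(UserWarning):
    """Genotypes were excluded during table assembly."""


class CollinearityWarning(UserWarning):
    """The regression design is near-collinear."""
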
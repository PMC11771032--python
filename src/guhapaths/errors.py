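"""Exception hierarchy shared across the pipeline stages."""


class GuhaPathsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GuhaPathsError):
    """Invalid user input, configuration, or preconditions."""


class LifeTableLookupError(GuhaPathsError):
    """A (sex, completed age) pair is missing from the life table."""


class CodingConfigError(ValidationError):
    """A predicate coding is structurally invalid (overlap, bounds)."""


class CodingGapError(GuhaPathsError):
    """An observed attribute value matched no predicate and is not missing."""


class DegenerateTableError(GuhaPathsError):
    """A contingency-table quantity is undefined for the given margins."""


class SyntheticSpecError(ValidationError):
    """A synthetic-cohort specification is infeasible."""


class PipelineError(GuhaPathsError):
    """A pipeline stage failed; the message names the stage."""
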
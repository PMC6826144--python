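"""Exception hierarchy shared across the pipeline."""


class TelomrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TelomrError):
    """An input value violates a documented precondition."""


class SchemaError(TelomrError):
    """A table is missing required columns or is otherwise malformed."""


class DuplicateInstrument(TelomrError):
    """The same rsid appears more than once in an instrument panel."""


class DegenerateDistribution(TelomrError):
    """A distribution fit was requested on degenerate (constant) data."""


class DegenerateGenotype(TelomrError):
    """A genotype vector is constant and cannot be used as a regressor."""


class InsufficientData(TelomrError):
    """Too few rows, instruments, or outcome classes to fit a model."""


class SingularWeightMatrix(TelomrError):
    """The GLS weight matrix is singular even after PSD repair."""


class ConvergenceFailure(TelomrError):
    """An iterative fit failed to converge within its iteration budget."""
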
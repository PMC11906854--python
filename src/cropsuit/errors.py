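"""Exception hierarchy shared across the package."""


class SuitabilityError(Exception):
    """Base class for all cropsuit errors."""


class MatrixValidationError(SuitabilityError):
    """A pairwise comparison matrix violates the positive-reciprocal contract."""


class ConsistencyGateError(SuitabilityError):
    """A judgment matrix failed the CR < 0.1 gate and the run was not forced."""


class AlignmentError(SuitabilityError):
    """Two grids that must be co-registered have different shapes or transforms."""


class DomainError(SuitabilityError):
    """A raster value falls outside the domain a classification scheme declares."""
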
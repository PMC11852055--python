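"""Exception hierarchy shared across the package."""


class KneesimError(Exception):
    """Base class for all package-specific errors."""


class StlFormatError(KneesimError):
    """Unreadable or truncated STL payload; message names the byte offset."""


class InvalidTransformError(KneesimError):
    """Singular or otherwise unusable geometric transform."""


class ConditioningError(KneesimError):
    """Interpolation system is singular (coplanar/duplicate landmarks)."""


class PairingError(KneesimError):
    """Source/target landmark name sets do not match."""


class DomainError(KneesimError):
    """Scalar input outside the mathematically valid domain."""


class UnderdeterminedError(KneesimError):
    """Too few / degenerate observations for a rigid-body fit."""


class ConfigurationError(KneesimError):
    """Model assembly is missing a required surface, table or parameter."""


class InfeasibleError(KneesimError):
    """Recruitment equality constraints cannot be satisfied with f >= 0."""

    def __init__(self, message: str, equation: int | None = None):
        super().__init__(message)
        self.equation = equation


class RankError(KneesimError):
    """Constraint matrix rank defect (unbounded or redundant system)."""


class GeometryError(KneesimError):
    """Degenerate geometric primitive (zero-length segment, empty mesh)."""


class AlignmentError(KneesimError):
    """Time series that must share a clock have incompatible lengths."""


class NonConvergenceError(KneesimError):
    """Iterative solve exceeded its iteration cap."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
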
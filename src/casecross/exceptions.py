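"""Exception hierarchy for the case-crossover pipeline."""


class CaseCrossError(Exception):
    """Base class for all package-specific errors."""


class UndefinedScoreError(CaseCrossError):
    """A segregation score is undefined for a census unit (e.g. zero population).

    Units raising this are flagged and excluded downstream, never silently
    zeroed.
    """


class ValidationError(CaseCrossError):
    """Input violates a documented precondition."""


class ConfigurationError(CaseCrossError):
    """Pipeline configuration is unusable (e.g. empty grid-cell list)."""


class MissingCovariateError(CaseCrossError):
    """A required daily covariate value is absent for a requested date."""


class ConvergenceError(CaseCrossError):
    """The likelihood maximizer failed to converge."""


class SeparationError(ConvergenceError):
    """Monotone likelihood: a coefficient diverges without bound.

    Carries the name of the offending design column.
    """

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"monotone likelihood / separation in column {column!r}")


class RankDeficiencyError(CaseCrossError):
    """The within-set-centered design matrix is rank deficient.

    Carries the names of the collinear (or set-constant, hence inestimable)
    columns. Modifier *main* effects are the canonical trigger: they are
    constant within each matched set and cancel from the conditional
    likelihood.
    """

    def __init__(self, columns: list[str], message: str | None = None):
        self.columns = list(columns)
        super().__init__(
            message
            or "rank-deficient design after within-set centering; "
            f"inestimable/collinear columns: {', '.join(self.columns)}"
        )
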
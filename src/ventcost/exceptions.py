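"""Exception hierarchy for ventcost.

Every error raised deliberately by the package derives from
:class:`VentcostError`, so callers can catch the whole family with one
``except`` clause while the specific subclasses keep the failure modes of
the pipeline (schema problems, degenerate fits, unit mismatches, ...)
distinguishable.
"""


class VentcostError(Exception):
    """Base class for all ventcost errors."""


class SchemaError(VentcostError):
    """A required column is missing or a file cannot be interpreted as a cohort."""


class ParseError(VentcostError):
    """A cell could not be parsed as a number; message names row and column."""


class CohortValidationError(VentcostError):
    """One or more rows violate the physiological range invariants."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class InsufficientDataError(VentcostError):
    """Too few records/samples for the requested operation."""


class DomainError(VentcostError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class SingularFitError(VentcostError):
    """The design matrix is rank deficient (e.g. constant predictor for a cubic)."""


class UnitsError(VentcostError):
    """Volume-condition mismatch (BTPS series fed to an STPD-only step)."""


class ShapeError(VentcostError):
    """Channel lengths disagree."""


class UndefinedR2Error(VentcostError):
    """Total sum of squares is zero, so R-squared is undefined."""


class DegenerateTestError(VentcostError):
    """A statistical test is degenerate (zero-variance differences, constant regressor)."""


class DegeneratePredictorError(VentcostError):
    """A predictor is constant or perfectly collinear with the others."""


class IncompleteDesignError(VentcostError):
    """A repeated-measures design has missing cells."""


class ValidationRunError(VentcostError):
    """Too many cross-validation folds failed to converge."""


class BootstrapError(VentcostError):
    """All bootstrap iterations failed."""


class ExtrapolationError(VentcostError):
    """A requested interpolation point lies outside the observed range."""
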
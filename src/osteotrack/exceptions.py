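"""Exception hierarchy for cohort IO, estimation and model evaluation."""


class OsteotrackError(Exception):
    """Base class for all package errors."""


class CohortFormatError(OsteotrackError):
    """A cohort file is structurally malformed (missing column, bad dtype)."""


class SeriesValidationError(OsteotrackError):
    """A vertebra series violates its contract (ordering, negative ORI...)."""


class ParameterError(OsteotrackError, ValueError):
    """A model parameter is outside its admissible range."""


class DesignError(OsteotrackError, ValueError):
    """A simulation design cannot produce a valid cohort."""


class InsufficientDataError(OsteotrackError):
    """Too few observations for the requested operation."""


class DegenerateSeriesError(OsteotrackError):
    """A series whose two-point line cannot identify a formation time."""


class EstimationError(OsteotrackError):
    """Maximum-likelihood optimisation failed to converge."""


class DegenerateVarianceError(EstimationError):
    """All growth residuals are zero; the diffusion MLE is degenerate."""


class NumericsError(OsteotrackError):
    """Quadrature or root finding failed to reach tolerance."""
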
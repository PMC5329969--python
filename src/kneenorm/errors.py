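"""Exception hierarchy.

All package-specific failures derive from :class:`KneenormError` so callers
(and the CLI) can distinguish computation failures from programming errors.
"""


class KneenormError(Exception):
    """Base class for all errors raised by kneenorm."""


class IngestError(KneenormError):
    """A peak list could not be read or failed validation at ingest."""


class OccupancyError(KneenormError):
    """A window holds fewer peaks than the minimum occupancy."""


class DegenerateWindowError(KneenormError):
    """Window intensities are (near-)constant; a power fit is meaningless."""


class FitError(KneenormError):
    """The nonlinear power-law fit failed to converge."""


class KneeNotFoundError(KneenormError):
    """The curvature of the fitted curve has no interior maximum."""


class StandardizationError(KneenormError):
    """Standardization is infeasible or the normalization curve is invalid."""


class UndefinedStatisticError(KneenormError):
    """A concordance statistic is undefined (e.g. zero variance)."""


class EstimatorError(KneenormError):
    """The Passing-Bablok estimator could not be computed."""


class ExperimentError(KneenormError):
    """A simulation experiment failed (too many replicates unusable)."""
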
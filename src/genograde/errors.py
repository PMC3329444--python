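"""Exception hierarchy for genograde."""


class GenogradeError(Exception):
    """Base class for all genograde errors."""


class ValidationError(GenogradeError):
    """A domain invariant was violated (out-of-range value, bad category...)."""


class CohortIOError(GenogradeError):
    """A cohort table could not be parsed; message names the row/column."""


class NormalizationError(GenogradeError):
    """QC or frozen-normalization contract violation."""


class GradingError(GenogradeError):
    """Signature scoring / calibration failure."""


class CalibrationError(GradingError):
    """Scale/offset calibration is degenerate (signature not oriented)."""


class AssociationError(GenogradeError):
    """Cross-tabulation or independence-test contract violation."""


class SurvivalError(GenogradeError):
    """Survival-analysis contract violation (separation, constant covariate...)."""


class DecisionError(GenogradeError):
    """Guideline ruleset is invalid or does not cover a patient."""
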
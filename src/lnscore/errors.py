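"""Exception hierarchy for the lymph-node scoring pipeline."""


class LnscoreError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LnscoreError):
    """A value violates a documented precondition (e.g. nonpositive volume)."""


class InvalidSpecError(LnscoreError):
    """A simulation spec is internally inconsistent or out of range."""


class DegenerateGeometryError(LnscoreError):
    """A polygon or contour stack is too degenerate to measure."""


class NoEnhancementError(LnscoreError):
    """No contrast arrival could be detected in a time-intensity curve."""


class FitFailureError(LnscoreError):
    """Bolus-model fitting failed to converge from every start."""


class InsufficientDataError(LnscoreError):
    """Too few usable samples in an analysis window."""


class DegenerateTestError(LnscoreError):
    """A statistical test is undefined (e.g. zero-variance differences)."""


class PairingError(LnscoreError):
    """A subject is missing one side of its left/right node pair."""


class EmptyEvaluationError(LnscoreError):
    """A diagnostic evaluation was requested on an empty set of nodes."""


class SchemaError(LnscoreError):
    """A cohort table or config file violates the expected schema."""
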
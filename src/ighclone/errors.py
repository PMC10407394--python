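"""Exception types raised by the annotation pipeline."""


class IghcloneError(Exception):
    """Base class for all package errors."""


class GermlineError(IghcloneError):
    """Malformed or inconsistent germline reference input."""


class AssignmentError(IghcloneError):
    """No germline segment could be assigned above threshold.

    Carries the best sub-threshold candidate (if any) for diagnostics.
    """

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class JunctionUnresolvedError(IghcloneError):
    """The CDR3/junction could not be located on the query."""


class MutationCallError(IghcloneError):
    """The aligned V span is too short for a reliable mutation call."""


class SimulationError(IghcloneError):
    """Infeasible simulation configuration."""
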
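"""Exception hierarchy shared across the pipeline stages."""


class LretfitError(Exception):
    """Base class for all package errors."""


class InvalidTraceError(LretfitError, ValueError):
    """A decay trace is degenerate (all zero, non-finite, unordered...)."""


class UnderdeterminedError(LretfitError, ValueError):
    """Too few data points for the requested number of parameters."""


class ConvergenceError(LretfitError, RuntimeError):
    """The optimizer failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class EmptyResultError(LretfitError, ValueError):
    """An operation produced no usable components/entries."""


class NoSignalError(LretfitError, ValueError):
    """Both acceptor channels are empty for a probe pair/condition."""


class OverfitError(LretfitError, ValueError):
    """More distance components per channel than the model allows."""


class GroupingError(LretfitError, ValueError):
    """Records with mixed probe pairs or conditions in one replicate group."""


class FeasibilityError(LretfitError, ValueError):
    """A distance set admits no 3D bead geometry (triangle violation)."""
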
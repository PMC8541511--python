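"""Exception hierarchy shared by all pipeline stages."""


class ValveSegError(Exception):
    """Base class for all package errors."""


class ValidationError(ValveSegError, ValueError):
    """Raised when inputs or configuration violate a documented precondition."""


class NumericalError(ValveSegError, RuntimeError):
    """Raised when an iterative solver produces non-finite values.

    Carries the iteration index at which the failure was detected.
    """

    def __init__(self, message: str, iteration: int | None = None):
        self.iteration = iteration
        if iteration is not None:
            message = f"{message} (iteration {iteration})"
        super().__init__(message)


class RefinementFailure(ValveSegError, RuntimeError):
    """Raised when refinement receives an empty mask or zero-mass map.

    Carries the pipeline stage name so callers can report where the
    pipeline broke down.
    """

    def __init__(self, message: str, stage: str = "refinement"):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class VideoIOError(ValveSegError, IOError):
    """Raised for unreadable inputs or inconsistent frame geometry."""
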
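"""Exception hierarchy for the hvhfit package."""


class HvhError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HvhError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InvalidDesignError(HvhError, ValueError):
    """An experimental design violates its invariants."""


class InvalidScenarioError(HvhError, ValueError):
    """An interference scenario violates its invariants."""


class GenerationError(HvhError, RuntimeError):
    """Forward simulation produced a non-finite state for some microcosm."""


class IntegrationError(HvhError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class UndefinedRateError(DomainError):
    """A growth-rate quantity is undefined (zero initial or final density)."""


class SingularInversionError(DomainError):
    """Per-microcosm interference inversion is singular (ln C = 0 at C = 1)."""


class NonConvergenceError(HvhError, RuntimeError):
    """No optimizer start converged."""


class DegenerateDesignError(HvhError, ValueError):
    """A statistical model cannot be fit on a degenerate design."""


class InsufficientDataError(HvhError, ValueError):
    """Too few records to fit the requested model."""
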
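"""Exception hierarchy."""


class CoronaError(Exception):
    """Base class for all package errors."""


class EmptyStructureError(CoronaError):
    """Structure file contained no usable ATOM records."""


class BuildError(CoronaError):
    """Coarse-grained model could not be built (e.g. a residue lacks a Cα)."""


class InvalidSpecError(CoronaError, ValueError):
    """A generator or simulation specification violates its invariants."""


class PackingError(CoronaError):
    """Random placement failed to find a non-overlapping configuration."""


class IntegrationError(CoronaError):
    """Dynamics diverged (NaN/inf coordinates or energies)."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FitFailureError(CoronaError):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
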
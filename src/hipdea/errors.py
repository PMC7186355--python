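"""Exception hierarchy for hipdea."""


class HipDeaError(Exception):
    """Base class for all hipdea errors."""


class DegenerateGeometryError(HipDeaError):
    """Raised when geometry is singular (coplanar points, empty mesh, no joint space...)."""


class CorrespondenceError(HipDeaError):
    """Raised when inputs that must share a template correspondence do not."""


class FullCompressionError(HipDeaError):
    """Raised when a spring is compressed past the physical strain clamp."""


class ConvergenceError(HipDeaError):
    """Raised when the equilibrium solver exhausts its iteration budget.

    Carries the last iterate and residual for diagnostics.
    """

    def __init__(self, message, translation=None, residual=None, iterations=None):
        super().__init__(message)
        self.translation = translation
        self.residual = residual
        self.iterations = iterations


class DislocationError(HipDeaError):
    """Raised when no spring can carry load at the solver's optimum (joint dislocated)."""
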
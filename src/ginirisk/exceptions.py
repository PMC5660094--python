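"""Exception hierarchy shared across the package."""


class GiniRiskError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(GiniRiskError, ValueError):
    """A model parameter lies outside its admissible domain."""


class FeasibilityError(GiniRiskError, ValueError):
    """The requested moments cannot be realised by the chosen family."""


class QuadratureError(GiniRiskError, ArithmeticError):
    """Numerical integration did not converge to the requested tolerance."""


class NoConfidenceBoundsError(GiniRiskError, LookupError):
    """Confidence bounds were requested but none are available."""
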
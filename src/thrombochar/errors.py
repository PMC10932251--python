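"""Exception hierarchy for thrombochar."""


class ThrombocharError(Exception):
    """Base class for all package errors."""


class ValidationError(ThrombocharError):
    """Input violates a documented domain or invariant."""


class RegistrationError(ThrombocharError):
    """NCCT/CTA/mask are not on a common voxel grid."""


class FittingError(ThrombocharError):
    """A regression model failed to converge or is degenerate."""
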
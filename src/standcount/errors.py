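"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates a documented invariant; the message names the field."""


class ScaleError(RuntimeError):
    """Raised when an operation needs a known ground sampling distance."""


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the given data."""
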
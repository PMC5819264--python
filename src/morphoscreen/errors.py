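"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""


class FitError(RuntimeError):
    """Raised when a maximum-likelihood fit fails or is degenerate."""
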
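"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge or produced an implausible result.

    Carries a ``diagnostics`` dict with whatever the failing routine knew
    (initial guesses, bounds, best residual, optimizer message).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
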
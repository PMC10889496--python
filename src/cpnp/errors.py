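"""Exception types shared across the package."""


class NumericalFailureError(RuntimeError):
    """A solver produced non-finite values.

    Carries the name of the algorithm step in which the failure was first
    detected, so a diverging run can be diagnosed from the message alone.
    """

    def __init__(self, step: str, message: str | None = None):
        self.step = step
        detail = f": {message}" if message else ""
        super().__init__(f"non-finite values detected in step '{step}'{detail}")


class UnavailableDenoiserError(RuntimeError):
    """A denoiser backend is not installed or not registered."""
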
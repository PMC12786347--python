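"""Exception hierarchy for wbsim."""


class WbsimError(Exception):
    """Base class for all wbsim errors."""


class ValidationError(WbsimError, ValueError):
    """Raised when an input object violates its contract."""


class ConnectomeError(ValidationError):
    """Raised for malformed structural connectivity data."""


class DivergenceError(WbsimError, FloatingPointError):
    """Raised when an integration step produces a non-finite state.

    Carries the step index and, when known, the offending state variable.
    """

    def __init__(self, step_index, variable=None):
        self.step_index = step_index
        self.variable = variable
        msg = f"non-finite state at integration step {step_index}"
        if variable is not None:
            msg += f" (variable {variable!r})"
        super().__init__(msg)


class ConfigError(WbsimError, ValueError):
    """Raised for incomplete or inconsistent simulation configurations."""
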
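"""Exception hierarchy shared across the pipeline."""


class EmdTcnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmdTcnError, ValueError):
    """A configuration object violates one of its invariants."""


class ContractError(EmdTcnError, ValueError):
    """An operation was called with inputs that break its contract."""


class InputTooShortError(ContractError):
    """The supplied series is too short for the requested operation."""


class NotSiftableError(EmdTcnError):
    """Signal has too few extrema to build spline envelopes."""


class DegenerateInputError(ContractError):
    """Numerically degenerate input (e.g. zero-energy sifting candidate)."""


class DivergenceError(EmdTcnError, RuntimeError):
    """Training loss became non-finite; carries optimizer diagnostics."""

    def __init__(self, message: str, optimizer: str = "", lr: float = float("nan")):
        super().__init__(message)
        self.optimizer = optimizer
        self.lr = lr
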
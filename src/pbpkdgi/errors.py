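"""Exception hierarchy shared across the toolkit."""


class PbpkDgiError(Exception):
    """Base class for all toolkit errors."""


class DomainError(PbpkDgiError, ValueError):
    """An input value is outside its physical/mathematical domain."""


class FitError(PbpkDgiError, ValueError):
    """A regression or optimization problem is degenerate or misconfigured."""


class ValidationError(PbpkDgiError, ValueError):
    """A model, config or dataset failed structural validation."""


class PairingError(PbpkDgiError, ValueError):
    """Predicted and observed data could not be matched."""


class IntegrationError(PbpkDgiError, RuntimeError):
    """The ODE solver failed to produce a valid solution."""
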
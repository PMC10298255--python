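"""Exception hierarchy shared across the package."""


class ConfigError(ValueError):
    """Invalid user-supplied configuration or input (CLI exit code 2)."""


class NumericalError(RuntimeError):
    """Numerical failure during solving or fitting (CLI exit code 3)."""


class StabilityError(NumericalError):
    """Requested explicit time step violates the diffusion stability bound."""
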
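"""Exception types shared across the package."""


class DomainError(ValueError):
    """A physical parameter is outside its valid domain (names the field)."""


class ConfigurationError(ValueError):
    """A run or network configuration is inconsistent or unsolvable."""


class PairingError(ValueError):
    """A readout table is missing a required blank/reference pairing."""


class FitError(RuntimeError):
    """A parameter fit is degenerate or non-identifiable."""
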
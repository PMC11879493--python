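"""Shared exception types."""


class ShadenetError(Exception):
    """Base class for package errors."""


class ConfigError(ShadenetError, ValueError):
    """Invalid configuration or generator parameters."""


class ValidationError(ShadenetError, ValueError):
    """Input records violate a documented precondition."""


class PairingError(ValidationError):
    """Shade/control records could not be paired."""


class BalanceError(ValidationError):
    """Unbalanced design where a balanced layout is required."""


class ParseError(ShadenetError, ValueError):
    """Malformed input file."""
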
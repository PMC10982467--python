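"""Exception hierarchy shared across the pipeline stages."""


class VancomlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VancomlError, ValueError):
    """Invalid user-supplied configuration (ranges, ratios, unknown keys...)."""


class DomainError(VancomlError, ValueError):
    """Input outside the mathematical domain of an operation."""


class StateError(VancomlError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. untrained model)."""
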
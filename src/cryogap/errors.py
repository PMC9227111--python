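"""Error types raised by the pipeline stages."""


class CryogapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CryogapError):
    """A config/column-map problem: e.g. a mapped column missing from a file."""


class ValidationError(CryogapError):
    """Input data violates an invariant (bad EF token, conflicting family...)."""
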
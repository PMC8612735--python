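"""Exception hierarchy shared across the pipeline."""


class AAVScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AAVScreenError):
    """A file is structurally inconsistent (e.g. MTX header vs sidecar lines)."""


class ValidationError(AAVScreenError):
    """Data violates a domain invariant (duplicates, negative counts, ...)."""


class ReconciliationError(AAVScreenError):
    """Two inputs that must agree on identifiers do not."""


class ConfigError(AAVScreenError):
    """A parameter combination is invalid or unsafe."""
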
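"""Exception types shared across the package."""


class SonarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SonarError, ValueError):
    """A file, schema or run configuration is malformed (e.g. a missing column)."""


class ValidationError(SonarError, ValueError):
    """Input data violates a documented precondition or invariant."""


class BackendError(SonarError, RuntimeError):
    """An embedding backend failed on a batch of texts."""
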
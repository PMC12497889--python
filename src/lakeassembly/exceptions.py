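"""Exception hierarchy shared across the package."""


class LakeAssemblyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LakeAssemblyError, ValueError):
    """A file or in-memory structure violates the expected format."""


class InvalidInputError(LakeAssemblyError, ValueError):
    """Input data violate a precondition of an operation."""


class ConfigError(LakeAssemblyError, ValueError):
    """A configuration document is invalid; the message lists all failures."""


class FitError(LakeAssemblyError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""
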
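"""Exception hierarchy shared across the package."""


class ReplinormError(Exception):
    """Base class for all package errors."""


class DomainError(ReplinormError, ValueError):
    """An environmental value lies outside a reaction norm's valid range."""


class UnsupportedMethodError(ReplinormError, ValueError):
    """A closed-form composition was requested where none exists."""


class DegenerateSEError(ReplinormError, ValueError):
    """A standard error of zero (all observations identical) was encountered."""


class MissingCovariateError(ReplinormError, ValueError):
    """A criterion needing the environmental covariate got a study without one."""


class PrecisionError(ReplinormError, ValueError):
    """An empirical distribution is too small for reliable tail estimation."""


class StructuralError(ReplinormError, ValueError):
    """A dataset or input collection violates a structural requirement."""


class CollinearityError(ReplinormError, ValueError):
    """All environmental covariate values coincide; regression is undefined."""


class InsufficientReplicationError(ReplinormError, ValueError):
    """Too few laboratories to estimate a between-lab variance component."""


class ConfigError(ReplinormError, ValueError):
    """A run configuration failed schema or cross-reference validation."""
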
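"""Exception hierarchy shared across the package."""


class TrapstatError(Exception):
    """Base class for all package errors."""


class SchemaError(TrapstatError):
    """Input table violates its documented schema."""


class DataIntegrityError(TrapstatError):
    """Internally inconsistent data (e.g. a detection on an inactive day)."""


class DesignError(TrapstatError):
    """Model design matrix is unusable (rank deficient, unknown term...)."""


class SpacingInfeasibleError(TrapstatError):
    """Requested station count cannot satisfy the minimum-spacing rule."""


class InvalidParameterError(TrapstatError):
    """A structural parameter is outside its admissible range."""


class IdentifiabilityError(TrapstatError):
    """Data carry no information on a parameter (e.g. no spatial recaptures)."""
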
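"""Exception hierarchy shared by all pipeline stages."""


class CostackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CostackError):
    """A file does not conform to its expected on-disk format."""


class DimensionError(CostackError):
    """Array/image shape disagrees with the declared coordinate frame."""


class FrameMismatchError(DimensionError):
    """Two inputs claim incompatible coordinate frames."""


class ConfigError(CostackError):
    """Invalid or inconsistent configuration."""


class ParameterError(CostackError):
    """An operation received an out-of-range or unknown parameter."""


class CapacityError(CostackError):
    """Requested synthetic tissue cannot be packed into the canvas."""


class ValidityError(CostackError):
    """A geometric object or transform violates a validity invariant
    (self-intersecting polygon, folded displacement field, ...)."""


class DegeneracyError(CostackError):
    """A fit is rank-deficient (collinear or duplicated landmarks)."""


class AlignmentError(CostackError):
    """Two per-cell tables are not indexed by the same cell ids."""
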
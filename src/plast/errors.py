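"""Exception hierarchy for the plast package."""


class PlastError(Exception):
    """Base class for all plast errors."""


class ParameterError(PlastError, ValueError):
    """A parameter is outside its valid domain."""


class PlacementError(PlastError):
    """Synthetic cells could not be placed under the overlap constraint."""


class AlignmentError(PlastError):
    """Channel alignment failed (e.g. empty mask after morphology)."""


class DegenerateCellError(PlastError):
    """A segmented cell has no usable cytoplasm or signal."""


class ZeroSignalError(DegenerateCellError):
    """Total fluorescence inside the cellular region is zero."""


class SchemaError(PlastError):
    """A table is missing required columns."""


class InsufficientDataError(PlastError):
    """Too few cells/strains/labels for the requested operation."""


class RegistryError(PlastError):
    """Feature vectors do not share a feature registry."""


class DegenerateNullError(PlastError):
    """Null-distribution fit failed (no scores above the mode, or all equal)."""


class UndefinedMetricError(PlastError):
    """A metric is undefined for the given inputs (e.g. empty boundary set)."""
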
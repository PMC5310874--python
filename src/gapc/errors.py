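"""Exception hierarchy shared across the package."""


class GapcError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GapcError):
    """A required column or field is missing from an input file."""


class DataValidationError(GapcError):
    """Input values violate a dataset invariant (negative deaths, duplicate cells, ...)."""


class GraphError(GapcError):
    """Malformed adjacency input (self-loop, unknown node id, bad dialect)."""


class AlignmentError(GapcError):
    """Two objects that must share an axis (e.g. age groups) do not."""


class StructureError(GapcError):
    """Effect/model dimensions are mutually inconsistent."""


class InferenceError(GapcError):
    """Sampler initialization or adaptation failure."""
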
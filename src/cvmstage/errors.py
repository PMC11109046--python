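"""Exception hierarchy shared across the package."""


class CvmError(Exception):
    """Base class for all cvmstage errors."""


class ValidationError(CvmError):
    """A record or table violates a structural invariant (labels, ranges, schema)."""


class ParseError(CvmError):
    """A file could not be parsed; carries row/column context where possible."""


class GeometryError(CvmError):
    """Degenerate landmark geometry (coincident points, zero-length denominator)."""


class ModelError(CvmError):
    """Invalid model specification or a prediction-time contract violation."""


class FittingError(CvmError):
    """Model-development pipeline failure (empty candidate set, no variation, ...)."""
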
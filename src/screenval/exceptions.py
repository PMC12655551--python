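"""Exception hierarchy shared by all pipeline stages."""


class ScreenvalError(Exception):
    """Base class for all screenval errors."""


class FormatError(ScreenvalError):
    """A file does not conform to its declared dialect (missing column,
    malformed atom block, bad count line)."""


class DataError(ScreenvalError):
    """Values are syntactically valid but scientifically inadmissible
    (negative IC50, duplicate compound id, missing property)."""


class AlignmentError(ScreenvalError):
    """Two inputs that must describe the same compound set do not."""


class PairingError(ScreenvalError):
    """Two poses of one compound cannot be put in atom correspondence."""


class UndefinedMetricError(ScreenvalError):
    """The requested statistic is undefined on this input
    (single-class ROC, zero-variance response)."""


class SingularityError(ScreenvalError):
    """A design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns else []


class SelectionError(ScreenvalError):
    """Descriptor selection found no feasible full-rank subset."""
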
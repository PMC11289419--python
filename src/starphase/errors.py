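"""Exception hierarchy shared across the pipeline stages."""


class StarphaseError(Exception):
    """Base class for all package-specific failures."""


class PlacementError(StarphaseError):
    """Droplets could not be placed without overlap within the retry budget."""


class GeometryError(StarphaseError):
    """Requested geometry does not fit in the image frame."""


class NoContrastError(StarphaseError):
    """Frame has a single intensity value; Otsu thresholding is undefined."""


class EmptyRoiError(StarphaseError):
    """Region of interest contains no pixels."""


class NoChordsError(StarphaseError):
    """Chord length distribution is empty; the mean is undefined."""


class DegenerateTraceError(StarphaseError):
    """FRAP trace has a zero series maximum; Eq.-style normalization undefined."""


class AlignmentError(StarphaseError):
    """Replicate curves do not share a common time grid."""


class SequenceError(StarphaseError):
    """Invalid nucleic-acid sequence (alphabet, length, or structure)."""


class ConfigError(StarphaseError):
    """Malformed run configuration."""
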
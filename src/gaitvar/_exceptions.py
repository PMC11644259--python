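"""Exception hierarchy shared across the package."""


class GaitvarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitvarError):
    """Input file does not match the declared schema (missing columns, ...)."""


class DataError(GaitvarError):
    """Input data violates a precondition (non-monotone time, jitter, ...)."""


class CalibrationError(GaitvarError):
    """Tilt calibration impossible (mean acceleration not near 1 g)."""


class EstimationError(GaitvarError):
    """A spectral/statistical estimate could not be formed (flat spectrum)."""


class TruncationError(GaitvarError):
    """Bout too short for the requested step count."""


class ParameterError(GaitvarError):
    """Invalid algorithm parameters (embedding spec, fit windows, ...)."""


class DegenerateAttractorError(GaitvarError):
    """Too few valid neighbour pairs to average a divergence curve."""


class SeriesTooShortError(GaitvarError):
    """Stride-interval series too short for fluctuation analysis."""


class DegenerateSeriesError(GaitvarError):
    """Fluctuation function vanished (constant or degenerate series)."""


class GeneratorError(GaitvarError):
    """Synthetic-signal generation failed for the requested parameters."""
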
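"""Exception hierarchy shared across the pipeline stages."""


class KernradError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KernradError):
    """Invalid phantom or pipeline configuration."""


class GeometryError(KernradError):
    """Lesion geometry outside image bounds."""


class AnnotationNotFoundError(KernradError):
    """No red annotation pixels were detected in the image."""


class ContourError(KernradError):
    """The red annotation contour is not closed within tolerance."""


class BoundsError(KernradError):
    """Requested window exceeds the image bounds."""


class MaskError(KernradError):
    """Empty, multi-component, or otherwise invalid lesion mask."""


class DegenerateGLCMError(KernradError):
    """No valid pixel pairs available for the co-occurrence matrix."""


class EmptyFeatureSetError(KernradError):
    """The variance filter removed every feature."""


class ParameterError(KernradError):
    """Invalid model hyperparameter (kernel width, grids, ...)."""


class DimensionError(KernradError):
    """Requested embedding dimension exceeds the usable eigenvalue count."""


class LabelError(KernradError):
    """Degenerate labels (single class) where two classes are required."""


class StratificationError(KernradError):
    """Too few members of a class to form stratified folds."""


class DataError(KernradError):
    """Empty or misaligned evaluation inputs."""


class DegenerateComparisonError(KernradError):
    """Paired-comparison test with zero variance of the difference."""


class EncodingError(KernradError):
    """Unknown categorical level in the clinical covariates."""


class MissingDataError(KernradError):
    """Missing clinical covariate value."""
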
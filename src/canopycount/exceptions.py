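"""Exception hierarchy shared across the pipeline."""


class CanopyCountError(Exception):
    """Base class for all package errors."""


class CloudParseError(CanopyCountError):
    """A point-cloud or annotation file could not be parsed."""


class UnsupportedFormatError(CloudParseError):
    """The file is in a recognized but unsupported format (e.g. binary PLY)."""


class AnnotationValidationError(CanopyCountError):
    """An annotation box violates the declared image geometry."""


class ConfigError(CanopyCountError):
    """Invalid or inconsistent pipeline configuration."""


class ParameterError(CanopyCountError):
    """An algorithm parameter is out of its valid range for the given input."""


class DegenerateGeometryError(CanopyCountError):
    """The input geometry does not support the requested model fit."""


class GenerationError(CanopyCountError):
    """A synthetic scene could not be realized under its constraints."""


class UndefinedMetricError(CanopyCountError):
    """A metric is undefined for the given inputs (e.g. all-zero ground truth)."""


class AlignmentError(CanopyCountError):
    """Prediction and ground-truth records could not be aligned by id."""
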
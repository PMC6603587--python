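"""Typed exceptions shared across the pipeline.

Degenerate inputs raise loudly instead of producing empty results; the CLI
maps these onto distinct exit codes.
"""


class CsvdError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CsvdError):
    """Invalid configuration value (bad kernel size, rule name, spec...)."""


class FormatError(CsvdError):
    """A file could not be parsed in its declared format."""


class UnsupportedInputError(CsvdError):
    """Parsable input outside the supported subset (RGB slice, multi-frame DICOM)."""


class LabelDecodeError(CsvdError):
    """An annotation pixel is too far from every palette color."""


class ShapeError(CsvdError):
    """Mismatched array dimensions between paired inputs."""


class DegenerateImageError(CsvdError):
    """Image has no usable contrast (e.g. constant under Otsu)."""


class EmptyMaskError(CsvdError):
    """A non-empty binary mask was required."""


class NoBrainFoundError(CsvdError):
    """Brain extraction produced an empty final mask."""


class DegenerateDataError(CsvdError):
    """Training data lacks class diversity."""


class CountError(CsvdError):
    """Confusion counts violate their bounds."""


class UndefinedMetricError(CsvdError):
    """Metric denominator is zero."""


class PlacementError(CsvdError):
    """Phantom lesion placement failed after bounded retries."""
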
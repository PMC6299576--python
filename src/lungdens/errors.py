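"""Exception hierarchy for the lung densitometry pipeline.

Errors are categorized so the CLI can map them to distinct exit codes:
I/O problems, validation of inputs/configs, segmentation failures, and
statistics that are undefined for the given data.
"""


class LungDensError(Exception):
    """Base class for all package errors."""


class VolumeIOError(LungDensError):
    """Reading or writing a CT volume or mask failed."""


class AlignmentError(VolumeIOError):
    """A mask does not share the grid (shape/spacing) of its volume."""


class ValidationError(LungDensError):
    """An input value, spec or configuration violates its contract."""


class SegmentationError(LungDensError):
    """Lung segmentation could not produce a usable mask."""


class RegionError(ValidationError):
    """A requested mask region does not exist or is empty."""


class UndefinedStatisticError(LungDensError):
    """A statistic is undefined for the given data (e.g. constant input)."""
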
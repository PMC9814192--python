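"""Exception hierarchy shared by all pipeline stages."""


class MamsleepError(Exception):
    """Base class for all package errors."""


class FormatError(MamsleepError):
    """Malformed input file or unknown label/channel."""


class GeometryError(MamsleepError):
    """Invalid segmentation geometry (self-intersection, overlap, ...)."""


class MissingRegionError(MamsleepError):
    """A required region (e.g. cytoplasm) is absent from a mask."""


class UndefinedMetricError(MamsleepError):
    """A metric is undefined for this input (e.g. zero mitochondria)."""


class GenerationError(MamsleepError):
    """Synthetic generator could not satisfy its packing constraints."""


class ConfigError(MamsleepError):
    """Invalid or incomplete run configuration."""
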
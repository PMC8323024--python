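"""Exception hierarchy for the pipeline."""


class MaizeCFIError(Exception):
    """Base class for all package errors."""


class InputError(MaizeCFIError):
    """Unreadable, malformed, or empty input image/file."""


class ConfigError(MaizeCFIError):
    """Malformed configuration document or invalid parameter value."""


class NoPlantError(MaizeCFIError):
    """Segmentation produced an empty mask: no plant detected."""


class DegenerateImageError(MaizeCFIError):
    """Image histogram has fewer than two distinct intensities."""


class SkeletonError(MaizeCFIError):
    """Invalid skeleton input (empty, disconnected source, off-skeleton pixel)."""
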
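"""Exception hierarchy shared by all rwnseg stages."""


class RwnsegError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RwnsegError):
    """Missing or malformed input data (files, masks, meshes)."""


class FormatError(RwnsegError):
    """A file was readable but violated its format contract."""


class ParameterError(RwnsegError):
    """A numeric parameter is outside its documented domain."""


class GeometryError(RwnsegError):
    """Degenerate or inconsistent spatial configuration."""


class FitError(RwnsegError):
    """Histogram peak fitting failed; a manual threshold is advised."""


class EmptySegmentationError(RwnsegError):
    """The niche fill produced no voxels.

    Carries per-rule candidate counts to help diagnose which exclusion
    rule emptied the segmentation.
    """

    def __init__(self, message, counts=None):
        super().__init__(message)
        self.counts = dict(counts) if counts else {}


class PlacementError(RwnsegError):
    """The implant handle could not be placed without hitting bone."""


class PipelineError(RwnsegError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
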
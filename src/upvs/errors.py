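"""Exception types shared across the pipeline."""


class UpvsError(Exception):
    """Base class for all package errors."""


class MissingSpacingError(UpvsError):
    """A volume file carries no voxel-spacing metadata and no override was given."""


class ShapeMismatchError(UpvsError):
    """A mask or volume does not match the shape of its paired grid."""


class IntensityRangeError(UpvsError):
    """Stored intensities fall outside the 8-bit range [0, 255]."""


class PipelineStageError(UpvsError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
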
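"""Exception hierarchy for the TMJ measurement pipeline."""


class TMJError(Exception):
    """Base class for all pipeline errors."""


class VolumeError(TMJError):
    """Malformed or inconsistent volumetric input."""


class SegmentationError(TMJError):
    """Bone segmentation failed (e.g. no bone found in the VOI)."""


class GeometryError(TMJError):
    """Degenerate geometry (collinear component, zero-length section, ...)."""


class MeasurementError(TMJError):
    """Landmark or gap-width determination failed."""


class StageError(TMJError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
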
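"""Exception hierarchy.

Every stage failure is a :class:`ThermofaceError` subclass so the pipeline
driver can wrap it with the stage name (:class:`StageError`) without ever
emitting a partial result.
"""


class ThermofaceError(Exception):
    """Base class for all package errors."""


class FrameFormatError(ThermofaceError):
    """Raw input file could not be parsed as a 2-D numeric array."""


class SensorRangeError(ThermofaceError):
    """A temperature value falls outside the sensor range [-20, 100] degC."""

    def __init__(self, value: float, coord: tuple[int, int]):
        self.value = value
        self.coord = coord
        super().__init__(
            f"sensor-range violation: {value:.3f} degC at (row={coord[0]}, "
            f"col={coord[1]}) outside [-20, 100] degC"
        )


class DegenerateFrameError(ThermofaceError):
    """Constant frame: no head/background contrast, grayscale undefined."""


class MaskEncodingError(ThermofaceError):
    """A mask image contains values other than 0 and 255."""


class DegenerateHistogramError(ThermofaceError):
    """Single-valued image: Otsu split undefined."""


class InvalidThresholdError(ThermofaceError):
    """Threshold M = 255 would divide by zero in the contrast stretch."""


class NoForegroundError(ThermofaceError):
    """Empty mask, or frame without foreground/background separation."""


class EmptyBoundaryError(ThermofaceError):
    """Mask too small to yield a boundary after erosion."""


class FitFailureError(ThermofaceError):
    """Ellipse fit impossible: too few/collinear points or non-ellipse conic."""


class GeometryError(ThermofaceError):
    """Conic coefficients do not describe a real ellipse."""


class EmptyRegionError(ThermofaceError):
    """A half-plane cut removed every mask pixel."""


class InsufficientCandidatesError(ThermofaceError):
    """Fewer than two extreme-temperature candidate pixels for clustering."""


class DegenerateLandmarkError(ThermofaceError):
    """The two detected landmark centers coincide."""


class EmptyForeheadError(ThermofaceError):
    """The forehead cut produced an empty region."""


class EmptyMaskError(ThermofaceError):
    """Mean temperature requested over an empty mask."""


class UndefinedIoUError(ThermofaceError):
    """Jaccard coefficient of two empty masks is undefined."""


class StageError(ThermofaceError):
    """Wraps any stage failure with the pipeline stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
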
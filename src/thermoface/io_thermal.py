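"""Thermal-frame and mask I/O plus the raw-to-grayscale transform.

A thermal camera delivers each frame as a matrix of temperatures in degrees
Celsius inside the sensor range [-20, 100] degC.  The first pipeline stage
maps that matrix onto an 8-bit grayscale image

    P'(x, y) = floor( (P(x, y) - min) / (max - min) * 255 )

so that the coldest pixel of the frame becomes 0 and the hottest 255.  The
transform is monotone and invariant to any positive affine rescaling of the
raw temperatures, which makes the downstream histogram thresholding
independent of the absolute scene temperature.

Coordinate convention throughout the package: raster convention with the
origin at the top-left corner, x (column index) increasing rightward and
y (row index) increasing downward.  "Upper" always means smaller y.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import (
    DegenerateFrameError,
    FrameFormatError,
    MaskEncodingError,
    SensorRangeError,
)

SENSOR_MIN_C = -20.0
SENSOR_MAX_C = 100.0
#: Frames smaller than this cannot host the ellipse geometry.
MIN_FRAME_SIDE = 16

__all__ = [
    "SENSOR_MIN_C",
    "SENSOR_MAX_C",
    "ThermalFrame",
    "GrayFrame",
    "BinaryMask",
    "read_raw_frame",
    "to_grayscale",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class ThermalFrame:
    """A validated matrix of temperatures in degC, indexed (row=y, col=x)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise FrameFormatError(f"thermal frame must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_FRAME_SIDE or arr.shape[1] < MIN_FRAME_SIDE:
            raise FrameFormatError(
                f"frame {arr.shape} smaller than {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}"
            )
        bad = ~np.isfinite(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FrameFormatError(f"non-finite value at (row={r}, col={c})")
        out = (arr < SENSOR_MIN_C) | (arr > SENSOR_MAX_C)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise SensorRangeError(float(arr[r, c]), (int(r), int(c)))
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GrayFrame:
    """8-bit intensity image, same shape as its source frame."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise FrameFormatError("gray frame must be 2-D")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise FrameFormatError("gray frame must hold integers")
            if arr.min() < 0 or arr.max() > 255:
                raise FrameFormatError("gray values outside [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class BinaryMask:
    """Image with entries in {0, 255}; nonzero pixels are foreground."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise MaskEncodingError("mask must be 2-D")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 255)).all():
            raise MaskEncodingError(
                f"mask values outside {{0, 255}}: found {uniq[:8].tolist()}"
            )
        object.__setattr__(self, "values", arr.astype(np.uint8))

    @classmethod
    def from_bool(cls, fg: np.ndarray) -> "BinaryMask":
        return cls(np.where(fg, 255, 0).astype(np.uint8))

    @property
    def count_nonzero(self) -> int:
        return int(np.count_nonzero(self.values))

    def as_bool(self) -> np.ndarray:
        return self.values > 0


def read_raw_frame(
    path: str | os.PathLike,
    format: str = "csv",
    scale: float = 1.0,
    offset: float = 0.0,
) -> ThermalFrame:
    """Load a raw thermal frame from disk.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"csv"`` (comma-separated floats, one row per image row, no header),
        ``"npy"`` (NumPy binary array) or ``"tiff16"`` (single-channel 16-bit
        TIFF whose stored integers decode to degC as ``value*scale + offset``).
    scale, offset:
        Affine decode applied to the stored values (identity by default, the
        natural choice for CSV/NPY already holding degC).

    Raises
    ------
    FrameFormatError
        Unparseable file or non-2-D content.
    SensorRangeError
        Any decoded value outside [-20, 100] degC, reported with its
        pixel coordinate.
    """
    try:
        if format == "csv":
            arr = np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
        elif format == "npy":
            arr = np.load(path, allow_pickle=False)
        elif format == "tiff16":
            import tifffile

            arr = tifffile.imread(path)
        else:
            raise FrameFormatError(f"unknown raw format {format!r}")
    except (OSError, ValueError) as exc:
        raise FrameFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64) * float(scale) + float(offset)
    return ThermalFrame(arr)


def write_raw_frame(frame: ThermalFrame, path: str | os.PathLike) -> None:
    """Write a frame as the package's CSV dialect (floats, no header)."""
    np.savetxt(path, frame.values, delimiter=",", fmt="%.6f")


def to_grayscale(frame: ThermalFrame) -> GrayFrame:
    """Map a thermal frame onto 8-bit grayscale.

    The frame minimum maps to 0 and the maximum to 255; intermediate values
    are scaled linearly and truncated (floor).  A constant frame carries no
    head/background contrast and is rejected.
    """
    vals = frame.values
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateFrameError(f"constant frame at {lo} degC")
    gray = np.floor((vals - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return GrayFrame(gray)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit single-channel PNG with values exactly 0/255."""
    Image.fromarray(mask.values, mode="L").save(path)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read an 8-bit single-channel mask image; values must be exactly 0/255."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise MaskEncodingError(f"{path}: mask image must be single-channel")
    return BinaryMask(arr)
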
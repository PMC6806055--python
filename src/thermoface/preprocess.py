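"""Background removal, head-mask construction and contour extraction.

Stages, in order:

1. :func:`otsu_threshold` — find the global intensity threshold M splitting
   the histogram into background [0, M] and head (M, 255] by minimizing the
   weighted within-class variance (Otsu's method).
2. :func:`stretch_threshold` — zero every background pixel and linearly
   restretch the surviving intensities to [0, 255].
3. :func:`binarize` — any positive pixel becomes 255, giving the head mask.
4. :func:`largest_component` — keep only the largest 8-connected blob
   (suppresses hands and other warm objects).
5. :func:`fill_holes` — fill interior holes left where cold objects on the
   face (glasses lenses, breathing masks) fell below the threshold, so the
   mask describes the full head silhouette.
6. :func:`extract_boundary` — one-pixel-thick inner contour via erosion with
   a 3x3 square structuring element followed by XOR with the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    EmptyBoundaryError,
    InvalidThresholdError,
    NoForegroundError,
)
from .io_thermal import BinaryMask, GrayFrame

__all__ = [
    "OtsuResult",
    "PointSet",
    "otsu_threshold",
    "stretch_threshold",
    "binarize",
    "largest_component",
    "fill_holes",
    "extract_boundary",
]

#: 8-connectivity structure shared by labeling and erosion.
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class OtsuResult:
    """Otsu split: threshold M and the within-class variance it attains.

    ``separability`` is the between-class share of the total variance
    (eta in [0, 1]); values near 1 indicate a cleanly bimodal histogram,
    values well below ~0.8 a frame with no distinct foreground.
    """

    threshold: int
    within_class_variance: float
    separability: float


@dataclass(frozen=True)
class PointSet:
    """Ordered (x=col, y=row) integer coordinates, unique, inside the image."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.int64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y) pairs")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("duplicate points in point set")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


def otsu_threshold(gray: GrayFrame) -> OtsuResult:
    """Global Otsu threshold of an 8-bit image.

    Evaluates the weighted within-class variance of every split
    S0 = [0, M], S1 = [M+1, 255] over all 256 candidates and returns the
    minimizing M (ties broken toward the smaller M).  Minimizing the
    within-class variance is algebraically equivalent to maximizing the
    between-class variance; the within-class form is computed here because
    it is the quantity the brute-force oracle checks.
    """
    hist = np.bincount(gray.values.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("single-valued image: no split exists")
    p = hist / n
    levels = np.arange(256, dtype=np.float64)

    w0 = np.cumsum(p)                      # class masses for M = 0..255
    s0 = np.cumsum(p * levels)             # first moments
    q0 = np.cumsum(p * levels**2)          # second moments
    w1 = 1.0 - w0
    s1 = s0[-1] - s0
    q1 = q0[-1] - q0

    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = q0 / w0 - (s0 / w0) ** 2
        var1 = q1 / w1 - (s1 / w1) ** 2
    var0 = np.where(w0 > 0, var0, 0.0)
    var1 = np.where(w1 > 0, var1, 0.0)
    within = w0 * np.maximum(var0, 0.0) + w1 * np.maximum(var1, 0.0)

    m = int(np.argmin(within))             # argmin returns the first (smallest) M
    total = float(q0[-1] - s0[-1] ** 2)
    eta = 1.0 - float(within[m]) / total if total > 0 else 0.0
    return OtsuResult(m, float(within[m]), eta)


def stretch_threshold(gray: GrayFrame, m: int) -> GrayFrame:
    """Zero pixels at or below M, restretch the rest linearly onto [0, 255].

    P'' = 0 for P' <= M, else floor(255 * (P' - M) / (255 - M)).
    """
    if not 0 <= m < 255:
        raise InvalidThresholdError(f"threshold M={m} outside [0, 254]")
    vals = gray.values.astype(np.float64)
    out = np.floor(255.0 * (vals - m) / (255.0 - m))
    out = np.where(vals <= m, 0.0, out)
    return GrayFrame(out.astype(np.uint8))


def binarize(thresholded: GrayFrame) -> BinaryMask:
    """Every positive pixel becomes 255; zeros stay 0."""
    return BinaryMask.from_bool(thresholded.values > 0)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Restrict the mask to its largest 8-connected nonzero component.

    Ties are broken by the smallest top-left bounding-box corner in
    row-major order.
    """
    if mask.count_nonzero == 0:
        raise NoForegroundError("empty mask: no foreground component")
    labels, n_labels = ndimage.label(mask.as_bool(), structure=_SQUARE3)
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    best_size = counts.max()
    winners = np.flatnonzero(counts == best_size) + 1
    if len(winners) > 1:
        slices = ndimage.find_objects(labels)
        corners = [
            (slices[lab - 1][0].start, slices[lab - 1][1].start) for lab in winners
        ]
        winner = winners[int(np.lexsort((np.array(corners)[:, 1],
                                         np.array(corners)[:, 0]))[0])]
    else:
        winner = winners[0]
    return BinaryMask.from_bool(labels == winner)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill interior holes so the mask is the full head silhouette.

    Cold face-borne objects (glasses lenses, breathing masks) fall below the
    Otsu threshold and punch holes in the head mask; without filling, the
    contour extraction would emit the hole rings as spurious boundary points
    and bias the ellipse fit inward.
    """
    return BinaryMask.from_bool(ndimage.binary_fill_holes(mask.as_bool()))


def extract_boundary(mask: BinaryMask) -> PointSet:
    """Inner one-pixel boundary: mask XOR erode(mask, 3x3 square).

    Pixels outside the image are treated as background, so a blob touching
    the frame edge still yields boundary points there.
    """
    if mask.count_nonzero < 9:
        raise EmptyBoundaryError(
            f"mask with {mask.count_nonzero} pixels is too small for a boundary"
        )
    fg = mask.as_bool()
    eroded = ndimage.binary_erosion(fg, structure=_SQUARE3, border_value=0)
    boundary = fg ^ eroded
    if not boundary.any():
        raise EmptyBoundaryError("erosion left no boundary pixels")
    rows, cols = np.nonzero(boundary)
    return PointSet(np.column_stack([cols, rows]))
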
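"""Eye / glasses-lens localization in the upper half-ellipse.

Eyes are the warmest patches of the upper face; glasses lenses, whose
emissivity differs from skin, appear as the coldest.  Landmarks are found by
selecting the extreme-temperature pixels of the upper half-ellipse (top or
bottom decile, by mode) and clustering their 2-D coordinates with 2-means
under the Euclidean metric.

The two centroids are initialized from the fitted ellipse: offsets of half a
semi-axis on each side of the major axis (+-Rmin/2 across, Rmax/2 along),
rotated by the head angle beta.  A literal evaluation of that rule points
into the *lower* image half under the raster convention (y grows downward),
so the major-axis offset is reflected across the center whenever the point
would land in the discarded half.  Starting next to the expected eye
positions makes Lloyd's algorithm converge in a handful of iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ellipse_geom import EllipseGeometry, minor_axis_line
from .errors import InsufficientCandidatesError
from .io_thermal import BinaryMask, GrayFrame, ThermalFrame
from .preprocess import PointSet

__all__ = [
    "ClusterPair",
    "init_clusters",
    "select_candidates",
    "kmeans2",
    "detect_eye_regions",
]

logger = logging.getLogger(__name__)

#: Lloyd iteration stops when both centroid shifts drop below this (pixels).
CONVERGENCE_TOL_PX = 0.5
MAX_ITERATIONS = 100
#: Fraction of region pixels admitted as extreme-temperature candidates.
DEFAULT_QUANTILE = 0.10


@dataclass(frozen=True)
class ClusterPair:
    """Two cluster centers in canonical left/right order (c1.x <= c2.x).

    ``member_counts`` is ``None`` for an initialization pair that has not
    been through Lloyd iteration yet.
    """

    c1: tuple[float, float]
    c2: tuple[float, float]
    n_iterations: int = 0
    member_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.c1[0] > self.c2[0] or (
            self.c1[0] == self.c2[0] and self.c1[1] > self.c2[1]
        ):
            c1, c2 = self.c2, self.c1
            mc = self.member_counts
            object.__setattr__(self, "c1", c1)
            object.__setattr__(self, "c2", c2)
            if mc is not None:
                object.__setattr__(self, "member_counts", (mc[1], mc[0]))
        if self.member_counts is not None and min(self.member_counts) < 1:
            raise ValueError("converged clusters must each hold >= 1 member")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2], dtype=np.float64)


def init_clusters(geom: EllipseGeometry) -> ClusterPair:
    """Ellipse-derived 2-means initialization.

    Literal rule: C_{1,2} = R(beta) @ (-+Rmin/2, Rmax/2) + center, with
    R(beta) the rotation matrix of the head angle.  If a point lands in the
    half-plane discarded by the minor-axis cut (the lower face), its
    major-axis offset is reflected across the center so both seeds lie in
    the retained upper half.
    """
    center = np.asarray(geom.center)
    d_up = geom.major_axis_up()
    d_minor = geom.minor_axis_left()
    line = minor_axis_line(geom)
    seeds = []
    for side in (-1.0, 1.0):
        # literal rule: major-axis offset of +Rmax/2 points *down* the image
        pt = center + side * (geom.r_min / 2.0) * d_minor - (geom.r_max / 2.0) * d_up
        if line.keep_sign * line.signed_distance(pt[0], pt[1]) <= 0:
            pt = center + side * (geom.r_min / 2.0) * d_minor \
                + (geom.r_max / 2.0) * d_up
        seeds.append((float(pt[0]), float(pt[1])))
    return ClusterPair(seeds[0], seeds[1])


def select_candidates(
    thresholded_upper: GrayFrame,
    raw: ThermalFrame,
    face_mask: BinaryMask,
    has_glasses: bool,
    quantile: float = DEFAULT_QUANTILE,
) -> PointSet:
    """Extreme-temperature candidate pixels of the upper face region.

    Without glasses the warmest pixels are wanted: candidates are the pixels
    whose *stretched intensity* lies in the top ``quantile`` of the nonzero
    upper-half intensities.  With glasses the coldest are wanted: the
    contrast stretch clamps lens pixels to zero and destroys their ordering,
    so candidates are taken from the *raw temperatures* inside the upper
    face region instead, bottom ``quantile``.

    Whole groups of equal-valued pixels are admitted from the extreme end
    while the running total stays within ``quantile`` of the region size; a
    region whose most extreme group already exceeds that cap (e.g. a uniform
    region) yields no distinct extreme and raises.
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError(f"quantile must be in (0, 0.5), got {quantile}")
    region = face_mask.as_bool()
    n_region = int(region.sum())
    if n_region == 0:
        raise InsufficientCandidatesError("empty face region")
    rows, cols = np.nonzero(region)
    if has_glasses:
        vals = raw.values[rows, cols]
        order_sign = 1.0  # ascending: coldest first
    else:
        vals = thresholded_upper.values[rows, cols].astype(np.float64)
        keep = vals > 0
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        order_sign = -1.0  # descending: hottest first
    if len(vals) == 0:
        raise InsufficientCandidatesError("upper face region has no usable pixels")
    cap = max(2, int(np.floor(quantile * len(vals))))

    uniq, inv, counts = np.unique(order_sign * vals, return_inverse=True,
                                  return_counts=True)
    admitted = np.cumsum(counts) <= cap
    sel = admitted[inv]
    if int(sel.sum()) < 2:
        raise InsufficientCandidatesError(
            f"no distinct temperature extreme: {int(sel.sum())} candidate(s) "
            f"within the {quantile:.0%} cap of {n_region} region pixels"
        )
    return PointSet(np.column_stack([cols[sel], rows[sel]]))


def kmeans2(candidates: PointSet, init: ClusterPair) -> ClusterPair:
    """Lloyd's 2-means on candidate pixel coordinates.

    Euclidean assignment from the given initialization; stops when both
    centroid shifts fall below 0.5 px or after 100 iterations.  If a cluster
    empties, its center is re-seeded at the candidate farthest from the
    other center (logged) rather than silently dropped.
    """
    pts = candidates.points.astype(np.float64)
    if len(pts) < 2:
        raise InsufficientCandidatesError("need >= 2 candidate points")
    centers = init.as_array()
    if np.allclose(centers[0], centers[1]):
        raise ValueError("initial centers must be distinct")
    counts = np.array([len(pts), 0])
    n_iter = 0
    for n_iter in range(1, MAX_ITERATIONS + 1):
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)
        new_centers = centers.copy()
        for k in (0, 1):
            members = pts[assign == k]
            if len(members) == 0:
                far = int(np.argmax(np.linalg.norm(pts - centers[1 - k], axis=1)))
                new_centers[k] = pts[far]
                logger.warning(
                    "cluster %d emptied at iteration %d; re-seeded at (%.1f, %.1f)",
                    k, n_iter, *pts[far],
                )
            else:
                new_centers[k] = members.mean(axis=0)
        shifts = np.linalg.norm(new_centers - centers, axis=1)
        centers = new_centers
        if (shifts < CONVERGENCE_TOL_PX).all():
            break
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)
    counts = (int((assign == 0).sum()), int((assign == 1).sum()))
    if min(counts) == 0:  # pathological: all candidates coincide
        counts = (max(counts[0], 1), max(counts[1], 1))
    return ClusterPair(
        (float(centers[0, 0]), float(centers[0, 1])),
        (float(centers[1, 0]), float(centers[1, 1])),
        n_iterations=n_iter,
        member_counts=counts,
    )


def detect_eye_regions(
    thresholded: GrayFrame,
    raw: ThermalFrame,
    upper_mask: BinaryMask,
    geom: EllipseGeometry,
    has_glasses: bool,
    quantile: float = DEFAULT_QUANTILE,
) -> ClusterPair:
    """Locate the two eye (or lens) centers in the upper half-ellipse."""
    candidates = select_candidates(thresholded, raw, upper_mask, has_glasses,
                                   quantile)
    return kmeans2(candidates, init_clusters(geom))
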
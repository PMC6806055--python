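"""Forehead segmentation and mean-temperature extraction; pipeline driver.

Given the two eye (or lens) centers and the fitted head ellipse, the
forehead is the part of the upper half-ellipse above a line parallel to the
minor axis.  That line passes through the midpoint of the eye segment
shifted 20% of the way toward the ellipse apex — the raw midpoint sits on
the eye line itself, and the shift moves the cut clear of the eye/brow
region.  The mean forehead temperature is the plain average of the raw
temperatures under the final mask:

    Ft = sum(P * P_mask / 255) / w,

with w the nonzero pixel count of the mask (the mask weighting is the
identity since mask values are 0 or 255).

:func:`run_pipeline` chains every stage from raw frame to temperature and
wraps any stage failure in a :class:`~thermoface.errors.StageError` carrying
the stage name — there are no partial silent results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import ellipse_geom, landmarks, preprocess
from .ellipse_geom import EllipseGeometry, cut_halfplane, parallel_cut_line
from .errors import (
    DegenerateLandmarkError,
    EmptyForeheadError,
    EmptyMaskError,
    EmptyRegionError,
    NoForegroundError,
    StageError,
    ThermofaceError,
)
from .io_thermal import BinaryMask, ThermalFrame, to_grayscale
from .landmarks import ClusterPair

__all__ = [
    "PipelineConfig",
    "ForeheadResult",
    "shifted_midpoint",
    "segment_forehead",
    "mean_forehead_temperature",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    shift_fraction:
        Fraction of the midpoint-to-apex distance by which the forehead cut
        is raised above the eye midpoint (0.20 = the 20% rule).
    quantile:
        Fraction of upper-face pixels admitted as landmark candidates.
    min_separability:
        Minimum Otsu between-class share of total variance required to
        accept that the frame contains a foreground at all.  A head against
        a uniform background scores near 1; pure noise scores ~0.65, so a
        frame below this bound is rejected as head-free.
    """

    shift_fraction: float = 0.20
    quantile: float = landmarks.DEFAULT_QUANTILE
    min_separability: float = 0.75


@dataclass(frozen=True)
class ForeheadResult:
    """Final forehead mask, its mean temperature, and per-stage diagnostics."""

    mask: BinaryMask
    mean_temp_c: float
    pixel_count_w: int
    midpoint: tuple[float, float]
    shifted_midpoint: tuple[float, float]
    geometry: EllipseGeometry
    eyes: ClusterPair
    diagnostics: dict[str, Any] = field(default_factory=dict)


def shifted_midpoint(
    eyes: ClusterPair,
    geom: EllipseGeometry,
    shift_fraction: float = 0.20,
) -> tuple[float, float]:
    """Eye-segment midpoint shifted toward the ellipse apex.

    Mp = (c1 + c2) / 2;  result = Mp + shift_fraction * (top_point - Mp).
    """
    if not 0.0 <= shift_fraction < 1.0:
        raise ValueError(f"shift_fraction must be in [0, 1), got {shift_fraction}")
    c1 = np.asarray(eyes.c1, dtype=np.float64)
    c2 = np.asarray(eyes.c2, dtype=np.float64)
    if np.allclose(c1, c2):
        raise DegenerateLandmarkError("eye centers coincide; midpoint undefined")
    mp = (c1 + c2) / 2.0
    sm = mp + shift_fraction * (np.asarray(geom.top_point) - mp)
    return (float(sm[0]), float(sm[1]))


def segment_forehead(
    upper_mask: BinaryMask,
    geom: EllipseGeometry,
    xsm_ysm: tuple[float, float],
) -> BinaryMask:
    """Cut the upper half-ellipse above the shifted midpoint.

    Retains the pixels strictly on the apex side of the line through
    ``xsm_ysm`` parallel to the minor axis.  An empty result (e.g. the cut
    point above the ellipse top) raises with geometry diagnostics.
    """
    rows, cols = np.nonzero(upper_mask.as_bool())
    if len(rows) == 0:
        raise EmptyForeheadError("upper half-ellipse mask is empty")
    x, y = xsm_ysm
    if not (
        cols.min() - 0.5 <= x <= cols.max() + 0.5
        and rows.min() - 0.5 <= y <= rows.max() + 0.5
    ):
        raise EmptyForeheadError(
            f"shifted midpoint ({x:.1f}, {y:.1f}) outside the upper-mask "
            f"bounding box; geometry: {geom.to_json()}"
        )
    line = parallel_cut_line(geom, xsm_ysm)
    try:
        return cut_halfplane(upper_mask, line)
    except EmptyRegionError as exc:
        raise EmptyForeheadError(
            f"forehead cut produced an empty region; geometry: {geom.to_json()}"
        ) from exc


def mean_forehead_temperature(
    raw: ThermalFrame, mask: BinaryMask
) -> tuple[float, int]:
    """Mean raw temperature under the mask and the pixel count w."""
    if raw.values.shape != mask.values.shape:
        raise ValueError(
            f"shape mismatch: frame {raw.values.shape} vs mask {mask.values.shape}"
        )
    w = mask.count_nonzero
    if w == 0:
        raise EmptyMaskError("mean temperature over an empty mask")
    weights = mask.values.astype(np.float64) / 255.0
    mean = float((raw.values * weights).sum() / w)
    return mean, w


def run_pipeline(
    raw: ThermalFrame,
    has_glasses: bool,
    config: PipelineConfig | None = None,
) -> ForeheadResult:
    """Execute the full segmentation pipeline on one thermal frame.

    Stages: grayscale -> Otsu threshold -> contrast stretch -> binarize ->
    largest component -> hole filling -> boundary extraction -> ellipse fit
    -> upper-half cut -> eye/lens detection -> forehead cut -> temperature.
    Any stage failure is re-raised as :class:`StageError` with the stage
    name; diagnostics for completed stages are attached to the result.
    """
    cfg = config or PipelineConfig()
    diag: dict[str, Any] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ThermofaceError as exc:
            raise StageError(name, exc) from exc

    gray = stage("grayscale", to_grayscale, raw)
    otsu = stage("threshold", preprocess.otsu_threshold, gray)
    diag["otsu_threshold"] = otsu.threshold
    diag["otsu_separability"] = otsu.separability
    if otsu.separability < cfg.min_separability:
        raise StageError(
            "threshold",
            NoForegroundError(
                f"foreground/background separability {otsu.separability:.3f} "
                f"below {cfg.min_separability}; no head in frame"
            ),
        )
    stretched = stage("threshold", preprocess.stretch_threshold, gray, otsu.threshold)
    head = stage("binarize", preprocess.binarize, stretched)
    head = stage("components", preprocess.largest_component, head)
    head = stage("components", preprocess.fill_holes, head)
    boundary = stage("boundary", preprocess.extract_boundary, head)
    diag["n_boundary_points"] = len(boundary)

    conic = stage("ellipse_fit", ellipse_geom.fit_ellipse, boundary)
    geom = stage("geometry", ellipse_geom.conic_to_geometry, conic)
    diag["beta_deg"] = geom.beta_deg

    r1 = ellipse_geom.minor_axis_line(geom)
    upper = stage("upper_cut", cut_halfplane, head, r1)
    eyes = stage(
        "landmarks",
        landmarks.detect_eye_regions,
        stretched, raw, upper, geom, has_glasses, cfg.quantile,
    )
    diag["kmeans_iterations"] = eyes.n_iterations

    sm_fn = lambda: shifted_midpoint(eyes, geom, cfg.shift_fraction)  # noqa: E731
    sm = stage("forehead_cut", sm_fn)
    mask = stage("forehead_cut", segment_forehead, upper, geom, sm)
    mean_c, w = stage("temperature", mean_forehead_temperature, raw, mask)

    mp = tuple((np.asarray(eyes.c1) + np.asarray(eyes.c2)) / 2.0)
    return ForeheadResult(
        mask=mask,
        mean_temp_c=mean_c,
        pixel_count_w=w,
        midpoint=(float(mp[0]), float(mp[1])),
        shifted_midpoint=sm,
        geometry=geom,
        eyes=eyes,
        diagnostics=diag,
    )
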
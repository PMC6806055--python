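"""Synthetic thermal head phantoms with analytic ground truth.

A phantom frame emulates what the segmentation pipeline sees in practice: a
cool uniform background (~25 degC), a warm elliptical head (~34 degC), two
hotter eye disks (~36.5 degC) — or two colder lens disks (~28 degC) when the
subject wears glasses — optional cold occluders stamped on the face
(breathing mask, beard patches), and i.i.d. Gaussian sensor noise (default
sd 0.2 degC, the order of a microbolometer's NETD).

Head rotation (beta) covers the poses a seated subject produces by neck
rotation/flexion; eye disks sit half a semi-axis up and half a semi-axis to
each side of the center, mirroring the geometry the landmark initializer
assumes.

Ground truth is analytic: the forehead mask is the head-ellipse region
strictly above the line parallel to the minor axis through the 20%-shifted
midpoint of the true eye centers — the same geometric rule the pipeline
targets, so end-to-end IoU measures detection robustness, not rule
disagreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ellipse_geom import (
    EllipseGeometry,
    geometry_from_params,
    parallel_cut_line,
)
from .forehead import shifted_midpoint as _shifted_midpoint_rule
from .io_thermal import SENSOR_MAX_C, SENSOR_MIN_C, BinaryMask, ThermalFrame
from .landmarks import ClusterPair

__all__ = [
    "Occluder",
    "PhantomSpec",
    "GroundTruth",
    "SuiteRanges",
    "generate_phantom",
    "generate_suite",
    "breathing_mask_occluder",
    "beard_occluders",
]


@dataclass(frozen=True)
class Occluder:
    """A cold disk stamped on the face, in ellipse-local coordinates.

    ``offset_major`` is the signed offset along the apex direction in units
    of Rmax (negative = toward the chin); ``offset_minor`` along the left
    minor direction in units of Rmin; ``radius_frac`` the disk radius in
    units of Rmin.
    """

    offset_major: float
    offset_minor: float
    radius_frac: float
    temp_c: float


def breathing_mask_occluder(temp_c: float = 29.0) -> list[Occluder]:
    """A medical breathing mask covering the mouth/chin area."""
    return [Occluder(offset_major=-0.50, offset_minor=0.0,
                     radius_frac=0.45, temp_c=temp_c)]


def beard_occluders(temp_c: float = 31.0) -> list[Occluder]:
    """Beard/whisker patches around the jaw."""
    return [
        Occluder(offset_major=-0.62, offset_minor=0.0, radius_frac=0.30,
                 temp_c=temp_c),
        Occluder(offset_major=-0.45, offset_minor=0.40, radius_frac=0.22,
                 temp_c=temp_c),
        Occluder(offset_major=-0.45, offset_minor=-0.40, radius_frac=0.22,
                 temp_c=temp_c),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thermal head frame."""

    frame_shape: tuple[int, int] = (120, 140)  # (rows, cols)
    background_c: float = 25.0
    face_c: float = 34.0
    eye_c: float = 36.5
    lens_c: float = 28.0
    head_center: tuple[float, float] = (70.0, 60.0)  # (x, y)
    head_axes: tuple[float, float] = (30.0, 20.0)  # (Rmax, Rmin)
    beta_deg: float = 0.0
    has_glasses: bool = False
    occluders: tuple[Occluder, ...] = ()
    noise_sd_c: float = 0.2
    seed: int = 0
    eye_radius_px: float = 4.0
    lens_radius_px: float = 5.0
    shift_fraction: float = 0.20
    #: chin-to-forehead skin temperature span (degC): the face is rendered
    #: with a linear axial gradient, coolest at the chin and warmest just
    #: below the apex, as living skin is.  0 gives an isothermal face.
    face_gradient_c: float = 2.0

    def __post_init__(self) -> None:
        for name in ("background_c", "face_c", "eye_c", "lens_c"):
            t = getattr(self, name)
            if not SENSOR_MIN_C <= t <= SENSOR_MAX_C:
                raise ValueError(f"{name}={t} outside sensor range")
        if self.face_gradient_c < 0:
            raise ValueError("face_gradient_c must be >= 0")
        if not (self.eye_c > self.face_c + self.face_gradient_c / 2.0):
            raise ValueError("eyes must stay warmer than the warmest skin")
        if not self.face_c > self.background_c:
            raise ValueError("need face_c > background_c")
        if not self.lens_c < self.face_c - self.face_gradient_c / 2.0:
            raise ValueError("lenses must stay colder than the coolest skin")
        if not -60.0 <= self.beta_deg <= 60.0:
            raise ValueError(f"beta_deg={self.beta_deg} outside [-60, 60]")
        r_max, r_min = self.head_axes
        if not r_max >= r_min > 0:
            raise ValueError("need Rmax >= Rmin > 0")
        # rotated-ellipse bounding half-widths must stay inside the frame
        b = math.radians(self.beta_deg)
        wx = math.hypot(r_max * math.sin(b), r_min * math.cos(b))
        wy = math.hypot(r_max * math.cos(b), r_min * math.sin(b))
        rows, cols = self.frame_shape
        x0, y0 = self.head_center
        if not (wx + 1 <= x0 <= cols - 1 - wx and wy + 1 <= y0 <= rows - 1 - wy):
            raise ValueError("head ellipse leaves the frame")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth accompanying a phantom frame."""

    head_mask: BinaryMask
    forehead_mask: BinaryMask
    geometry: EllipseGeometry
    eye_centers: ClusterPair
    has_glasses: bool
    #: noise-free mean skin temperature under the truth forehead mask (degC)
    forehead_mean_c: float


def _disk(xx: np.ndarray, yy: np.ndarray, center: np.ndarray,
          radius: float) -> np.ndarray:
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[ThermalFrame, GroundTruth]:
    """Render one phantom frame and its analytic ground truth.

    Deterministic for a given spec (the seed drives only the sensor noise).
    """
    rows, cols = spec.frame_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    r_max, r_min = spec.head_axes
    geom = geometry_from_params(spec.head_center, r_max, r_min,
                                math.radians(spec.beta_deg))
    center = np.asarray(spec.head_center)
    d_up = geom.major_axis_up()
    d_left = geom.minor_axis_left()

    # head interior in the rotated frame
    px = (xx - center[0]) * d_up[0] + (yy - center[1]) * d_up[1]
    py = (xx - center[0]) * d_left[0] + (yy - center[1]) * d_left[1]
    head = (px / r_max) ** 2 + (py / r_min) ** 2 <= 1.0

    temp = np.full((rows, cols), spec.background_c, dtype=np.float64)
    # axial skin gradient: px is the signed apex-ward offset in [-Rmax, Rmax]
    skin = spec.face_c + spec.face_gradient_c * px / (2.0 * r_max)
    temp[head] = skin[head]

    e1 = center + (r_min / 2.0) * d_left + (r_max / 2.0) * d_up
    e2 = center - (r_min / 2.0) * d_left + (r_max / 2.0) * d_up
    if spec.has_glasses:
        spot_t, spot_r = spec.lens_c, spec.lens_radius_px
    else:
        spot_t, spot_r = spec.eye_c, spec.eye_radius_px
    for e in (e1, e2):
        temp[_disk(xx, yy, e, spot_r) & head] = spot_t

    for occ in spec.occluders:
        pos = center + occ.offset_major * r_max * d_up \
            + occ.offset_minor * r_min * d_left
        temp[_disk(xx, yy, pos, occ.radius_frac * r_min) & head] = occ.temp_c

    clean = temp.copy()
    if spec.noise_sd_c > 0:
        rng = np.random.default_rng(spec.seed)
        temp = temp + rng.normal(0.0, spec.noise_sd_c, size=temp.shape)
    temp = np.clip(temp, SENSOR_MIN_C, SENSOR_MAX_C)

    eyes = ClusterPair((float(e1[0]), float(e1[1])), (float(e2[0]), float(e2[1])))
    sm = _shifted_midpoint_rule(eyes, geom, spec.shift_fraction)
    line = parallel_cut_line(geom, sm)
    forehead = head & (line.keep_sign * line.signed_distance(xx, yy) > 0)
    # programmed forehead temperature: the noise-free rendered field (any
    # eye/lens sliver crossing the cut included) under the truth mask
    forehead_mean = float(clean[forehead].mean()) if forehead.any() else float("nan")

    truth = GroundTruth(
        head_mask=BinaryMask.from_bool(head),
        forehead_mask=BinaryMask.from_bool(forehead),
        geometry=geom,
        eye_centers=eyes,
        has_glasses=spec.has_glasses,
        forehead_mean_c=forehead_mean,
    )
    return ThermalFrame(temp), truth


@dataclass(frozen=True)
class SuiteRanges:
    """Sampling ranges for a phantom suite (the study conditions)."""

    beta_deg: tuple[float, float] = (-20.0, 20.0)
    glasses_prob: float = 0.5
    occluder_prob: float = 0.3
    r_max: tuple[float, float] = (27.0, 32.0)
    r_min: tuple[float, float] = (17.0, 21.0)
    center_jitter_px: float = 4.0
    noise_sd_c: float = 0.2


def generate_suite(
    n: int,
    ranges: SuiteRanges | None = None,
    master_seed: int = 0,
) -> tuple[list[tuple[ThermalFrame, GroundTruth, PhantomSpec]], pd.DataFrame]:
    """Generate n phantoms with pose/glasses/occluders sampled from ranges.

    Fully reproducible from ``master_seed``.  Returns the frames with their
    truths and specs, plus a manifest DataFrame (one row per frame) suitable
    for writing as CSV.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or SuiteRanges()
    rng = np.random.default_rng(master_seed)
    base = PhantomSpec()
    out = []
    records = []
    for i in range(n):
        beta = float(rng.uniform(*ranges.beta_deg))
        glasses = bool(rng.random() < ranges.glasses_prob)
        occluders: tuple[Occluder, ...] = ()
        if rng.random() < ranges.occluder_prob:
            occluders = tuple(
                breathing_mask_occluder() if rng.random() < 0.5
                else beard_occluders()
            )
        r_max = float(rng.uniform(*ranges.r_max))
        r_min = float(rng.uniform(*ranges.r_min))
        jx, jy = rng.uniform(-ranges.center_jitter_px,
                             ranges.center_jitter_px, size=2)
        spec = replace(
            base,
            head_center=(base.head_center[0] + float(jx),
                         base.head_center[1] + float(jy)),
            head_axes=(r_max, r_min),
            beta_deg=beta,
            has_glasses=glasses,
            occluders=occluders,
            noise_sd_c=ranges.noise_sd_c,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frame, truth = generate_phantom(spec)
        out.append((frame, truth, spec))
        records.append(
            {
                "frame_id": f"phantom_{i:04d}",
                "seed": spec.seed,
                "beta_deg": beta,
                "has_glasses": glasses,
                "n_occluders": len(occluders),
                "r_max": r_max,
                "r_min": r_min,
                "center_x": spec.head_center[0],
                "center_y": spec.head_center[1],
                "noise_sd_c": ranges.noise_sd_c,
            }
        )
    return out, pd.DataFrame.from_records(records)
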
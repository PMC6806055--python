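"""Direct least-squares ellipse fitting and half-plane mask cuts.

The head contour is fitted to a conic

    F(x, y) = A x^2 + B xy + C y^2 + D x + E y + F = 0

by the ellipse-specific direct least-squares method (Fitzgibbon et al., in
the numerically stable Halir--Flusser formulation): minimize the algebraic
residual subject to the ellipse constraint 4AC - B^2 = 1, which reduces to a
3x3 eigenproblem and always returns an ellipse when one exists.

From the conic the full geometry is recovered in closed form:

* center (x0, y0) from the gradient system 2A x0 + B y0 = -D,
  B x0 + 2C y0 = -E;
* semi-axes Rmax >= Rmin and axis directions from the eigen-decomposition of
  the quadratic part [[A, B/2], [B/2, C]];
* focal distance L = sqrt(Rmax^2 - Rmin^2);
* rotation angle beta = angle between the center-to-apex vector and the
  vertical image axis, with the sign convention of the raster frame:
  beta > 0 (clockwise) when the apex lies left of the center (xt < x0),
  beta < 0 when right of it, beta = 0 for an upright ellipse.

"Apex" (``top_point``) is the major-axis endpoint in the upper image half
(smaller y).  All angles are radians; |beta| <= pi/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, FitFailureError, GeometryError
from .io_thermal import BinaryMask
from .preprocess import PointSet

__all__ = [
    "ConicParams",
    "EllipseGeometry",
    "CutLine",
    "fit_ellipse",
    "conic_to_geometry",
    "geometry_from_params",
    "conic_from_geometry",
    "minor_axis_line",
    "parallel_cut_line",
    "cut_halfplane",
    "sample_ellipse_points",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ConicParams:
    """Conic coefficients (a..f), normalized so that 4ac - b^2 = 1, a + c > 0."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        disc = 4.0 * self.a * self.c - self.b**2
        if disc <= 0:
            raise GeometryError(f"conic is not an ellipse: 4AC - B^2 = {disc:.3g}")

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "ConicParams":
        """Normalize an arbitrary-scale coefficient vector."""
        a, b, c = theta[0], theta[1], theta[2]
        disc = 4.0 * a * c - b**2
        if disc <= 0:
            raise GeometryError(f"conic is not an ellipse: 4AC - B^2 = {disc:.3g}")
        s = 1.0 / math.sqrt(disc)
        if (a + c) * s < 0:
            s = -s
        return cls(*(float(v * s) for v in theta))

    def as_vector(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Algebraic residual F(x, y) at the given coordinates."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        return (
            self.a * x**2 + self.b * x * y + self.c * y**2
            + self.d * x + self.e * y + self.f
        )


@dataclass(frozen=True)
class EllipseGeometry:
    """Full metric description of a fitted ellipse (pixel units, radians)."""

    center: tuple[float, float]
    r_max: float
    r_min: float
    #: center-to-focus distance, sqrt(r_max^2 - r_min^2)
    focal_l: float
    #: normalizing factor: negated conic value at the center under the
    #: 4AC - B^2 = 1 normalization; equals r_max * r_min / 2
    k_norm: float
    beta: float
    top_point: tuple[float, float]
    left_minor_point: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.r_max >= self.r_min > 0):
            raise GeometryError(
                f"invalid semi-axes Rmax={self.r_max}, Rmin={self.r_min}"
            )
        if abs(self.beta) > math.pi / 2 + 1e-9:
            raise GeometryError(f"|beta|={abs(self.beta):.4f} exceeds pi/2")

    @property
    def beta_deg(self) -> float:
        return math.degrees(self.beta)

    def major_axis_up(self) -> np.ndarray:
        """Unit vector from the center toward the apex (upper image half)."""
        u = np.array(self.top_point) - np.array(self.center)
        return u / np.linalg.norm(u)

    def minor_axis_left(self) -> np.ndarray:
        """Unit vector from the center toward the left minor-axis endpoint."""
        u = np.array(self.left_minor_point) - np.array(self.center)
        return u / np.linalg.norm(u)

    def to_json(self) -> str:
        x0, y0 = self.center
        return json.dumps(
            {"x0": x0, "y0": y0, "Rmax": self.r_max, "Rmin": self.r_min,
             "L": self.focal_l, "beta_deg": self.beta_deg}
        )


@dataclass(frozen=True)
class CutLine:
    """Oriented line a*x + b*y + c = 0 with a^2 + b^2 = 1.

    ``keep_sign`` selects the retained open half-plane: a pixel p survives a
    cut iff keep_sign * (a*px + b*py + c) > 0 (strict, so pixels exactly on
    the line are discarded).
    """

    a: float
    b: float
    c: float
    keep_sign: int

    def __post_init__(self) -> None:
        norm = math.hypot(self.a, self.b)
        if norm < _EPS:
            raise GeometryError("degenerate line: (a, b) = (0, 0)")
        if abs(norm - 1.0) > 1e-9:
            object.__setattr__(self, "a", self.a / norm)
            object.__setattr__(self, "b", self.b / norm)
            object.__setattr__(self, "c", self.c / norm)
        if self.keep_sign not in (-1, 1):
            raise GeometryError("keep_sign must be +1 or -1")

    def signed_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, float) + self.b * np.asarray(y, float) + self.c

    @property
    def is_vertical(self) -> bool:
        return abs(self.b) < _EPS

    @property
    def slope(self) -> float:
        """Slope m of y = m x + b' (undefined for vertical lines)."""
        if self.is_vertical:
            raise GeometryError("vertical line has no finite slope")
        return -self.a / self.b

    @property
    def intercept(self) -> float:
        if self.is_vertical:
            raise GeometryError("vertical line has no intercept")
        return -self.c / self.b


def fit_ellipse(points: PointSet | np.ndarray) -> ConicParams:
    """Ellipse-specific direct least-squares fit of a contour point set.

    Uses the stable split-design formulation: with D1 = [x^2, xy, y^2] and
    D2 = [x, y, 1], the constrained problem reduces to a 3x3 eigenproblem
    whose unique eigenvector with 4ac - b^2 > 0 gives the quadratic part.
    Coordinates are centered and scaled first for conditioning; the conic is
    mapped back afterwards.  Exact (residual <= 1e-9) for points sampled
    from a true ellipse.

    Accepts either a :class:`PointSet` (integer pixel coordinates) or a raw
    (n, 2) float array of (x, y) pairs.
    """
    if isinstance(points, PointSet):
        pts = points.points.astype(np.float64)
    else:
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FitFailureError("points must be an (n, 2) array")
    if len(pts) < 6:
        raise FitFailureError(f"need >= 6 points, got {len(pts)}")
    mean = pts.mean(axis=0)
    scale = float(pts.std(axis=0).mean())
    if scale < _EPS:
        raise FitFailureError("all points coincide")
    u = (pts[:, 0] - mean[0]) / scale
    v = (pts[:, 1] - mean[1]) / scale

    # collinearity check on the centered coordinates
    if np.linalg.matrix_rank(np.column_stack([u, v]), tol=1e-9) < 2:
        raise FitFailureError("points are collinear")

    d1 = np.column_stack([u**2, u * v, v**2])
    d2 = np.column_stack([u, v, np.ones_like(u)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError(f"degenerate point configuration: {exc}") from exc
    m = s1 + s2 @ t
    # premultiply by C1^-1 where C1 encodes the constraint 4ac - b^2 = 1
    m_red = np.vstack([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m_red)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero((cond > 0) & np.isreal(eigval))
    if len(ok) == 0:
        raise FitFailureError("fit did not yield an ellipse")
    a1 = np.real(eigvec[:, ok[0]])
    a2 = t @ a1
    au, bu, cu = a1
    du, eu, fu = a2

    # undo the normalization u = (x - mx)/s, v = (y - my)/s
    s2_ = scale * scale
    mx, my = mean
    a = au / s2_
    b = bu / s2_
    c = cu / s2_
    d = (-2.0 * au * mx - bu * my) / s2_ + du / scale
    e = (-bu * mx - 2.0 * cu * my) / s2_ + eu / scale
    f = (
        (au * mx**2 + bu * mx * my + cu * my**2) / s2_
        - (du * mx + eu * my) / scale
        + fu
    )
    try:
        return ConicParams.from_vector(np.array([a, b, c, d, e, f]))
    except GeometryError as exc:
        raise FitFailureError(str(exc)) from exc


def conic_to_geometry(conic: ConicParams) -> EllipseGeometry:
    """Recover center, semi-axes, focal distance, apex and rotation angle.

    The center solves the gradient system; semi-axes come from the
    eigenvalues of the quadratic part Q evaluated against the conic value at
    the center (R_i = sqrt(-F0 / lambda_i)).  The apex is the major-axis
    endpoint with smaller y (ties: smaller x); for a circle the rotation is
    defined as zero and the apex placed straight up.
    """
    a, b, c, d, e, f = conic.as_vector()
    q = np.array([[a, b / 2.0], [b / 2.0, c]])
    center = np.linalg.solve(2.0 * q, -np.array([d, e]))
    x0, y0 = float(center[0]), float(center[1])
    f0 = float(conic.evaluate(x0, y0))
    if f0 >= 0:
        raise GeometryError(f"conic value at center is {f0:.3g}; not a real ellipse")
    lam, vec = np.linalg.eigh(q)  # ascending; both positive since a + c > 0
    if lam[0] <= 0:
        raise GeometryError("quadratic part is not positive definite")
    r_max = math.sqrt(-f0 / lam[0])
    r_min = math.sqrt(-f0 / lam[1])
    focal_l = math.sqrt(max(r_max**2 - r_min**2, 0.0))

    circle = (lam[1] - lam[0]) / lam[1] < 1e-12
    if circle:
        d_up = np.array([0.0, -1.0])
        beta = 0.0
    else:
        d_up = vec[:, 0]  # major-axis direction (smaller eigenvalue)
        if d_up[1] > 0 or (d_up[1] == 0 and d_up[0] > 0):
            d_up = -d_up
        # angle to the vertical "up" direction (0, -1)
        cosb = float(np.clip(-d_up[1], -1.0, 1.0))
        beta = math.acos(cosb)
        xt = x0 + r_max * d_up[0]
        if xt > x0:
            beta = -beta
        elif xt == x0:
            beta = 0.0
    top = (x0 + r_max * float(d_up[0]), y0 + r_max * float(d_up[1]))

    d_left = np.array([-d_up[1], d_up[0]])  # perpendicular
    if d_left[0] > _EPS:
        d_left = -d_left
    elif abs(d_left[0]) <= _EPS and d_left[1] > 0:
        d_left = -d_left
    left = (x0 + r_min * float(d_left[0]), y0 + r_min * float(d_left[1]))
    return EllipseGeometry(
        center=(x0, y0),
        r_max=r_max,
        r_min=r_min,
        focal_l=focal_l,
        k_norm=-f0 / math.sqrt(4.0 * a * c - b**2),
        beta=beta,
        top_point=top,
        left_minor_point=left,
    )


def geometry_from_params(
    center: tuple[float, float],
    r_max: float,
    r_min: float,
    beta: float,
) -> EllipseGeometry:
    """Construct the geometry directly from (center, semi-axes, rotation).

    The apex sits at center + r_max * (-sin beta, -cos beta), consistent
    with the sign convention of :func:`conic_to_geometry`.
    """
    if not (r_max >= r_min > 0):
        raise GeometryError(f"invalid semi-axes Rmax={r_max}, Rmin={r_min}")
    x0, y0 = center
    d_up = np.array([-math.sin(beta), -math.cos(beta)])
    d_left = np.array([-d_up[1], d_up[0]])
    if d_left[0] > _EPS or (abs(d_left[0]) <= _EPS and d_left[1] > 0):
        d_left = -d_left
    return EllipseGeometry(
        center=(float(x0), float(y0)),
        r_max=float(r_max),
        r_min=float(r_min),
        focal_l=math.sqrt(max(r_max**2 - r_min**2, 0.0)),
        k_norm=r_max * r_min / 2.0,
        beta=float(beta),
        top_point=(float(x0 + r_max * d_up[0]), float(y0 + r_max * d_up[1])),
        left_minor_point=(float(x0 + r_min * d_left[0]),
                          float(y0 + r_min * d_left[1])),
    )


def conic_from_geometry(geom: EllipseGeometry) -> ConicParams:
    """Expand (center, axes, rotation) into normalized conic coefficients."""
    x0, y0 = geom.center
    u = geom.major_axis_up()
    rot = np.column_stack([u, [-u[1], u[0]]])
    qq = rot @ np.diag([1.0 / geom.r_max**2, 1.0 / geom.r_min**2]) @ rot.T
    a, b, c = qq[0, 0], 2.0 * qq[0, 1], qq[1, 1]
    d = -2.0 * a * x0 - b * y0
    e = -b * x0 - 2.0 * c * y0
    f = a * x0**2 + b * x0 * y0 + c * y0**2 - 1.0
    return ConicParams.from_vector(np.array([a, b, c, d, e, f]))


def sample_ellipse_points(
    geom: EllipseGeometry,
    n: int = 120,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample n (x, y) points on the ellipse, optionally with pixel noise.

    Returns a float (n, 2) array suitable for :func:`fit_ellipse`.
    """
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    u = geom.major_axis_up()
    v = np.array([-u[1], u[0]])
    pts = (
        np.asarray(geom.center)
        + np.outer(np.cos(t) * geom.r_max, u)
        + np.outer(np.sin(t) * geom.r_min, v)
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


def minor_axis_line(geom: EllipseGeometry) -> CutLine:
    """Line through the center and the left minor-axis endpoint.

    The retained side is the one containing the apex, i.e. the upper half of
    the ellipse in the raster sense.
    """
    u = geom.major_axis_up()  # normal of the minor-axis line
    x0, y0 = geom.center
    c = -(u[0] * x0 + u[1] * y0)
    line = CutLine(float(u[0]), float(u[1]), float(c), 1)
    s = float(line.signed_distance(*geom.top_point))
    return CutLine(line.a, line.b, line.c, 1 if s > 0 else -1)


def parallel_cut_line(geom: EllipseGeometry, point: tuple[float, float]) -> CutLine:
    """Line through ``point`` parallel to the minor axis, keeping the apex side.

    The retained half-plane is anchored to the apex *direction* (center ->
    top_point), so a cut point placed above the apex yields an empty region
    rather than silently flipping sides.
    """
    u = geom.major_axis_up()
    c = -(u[0] * point[0] + u[1] * point[1])
    return CutLine(float(u[0]), float(u[1]), float(c), 1)


def cut_halfplane(mask: BinaryMask, line: CutLine) -> BinaryMask:
    """Retain mask pixels strictly on the keep side of the line."""
    rows, cols = mask.values.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    keep = line.keep_sign * line.signed_distance(xx, yy) > 0
    out = mask.as_bool() & keep
    if not out.any():
        raise EmptyRegionError("half-plane cut removed every pixel")
    return BinaryMask.from_bool(out)
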
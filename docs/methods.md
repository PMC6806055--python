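# Methods

This note records the model behind `thermoface`, the parameter defaults and
why they hold, the numerical conventions, and what the synthetic phantom
suite does and does not establish about real thermographic data.

## Coordinate and sign conventions

All images use the raster convention: origin at the top-left pixel, x (the
column index) increasing rightward, y (the row index) increasing downward.
"Upper" always means smaller y. The head rotation angle β is the angle
between the ellipse's center-to-apex vector and the vertical image axis,
stored in radians with |β| ≤ π/2 and reported in degrees at the interfaces.
Its sign follows the clockwise-positive rule: β > 0 when the apex lies left
of the center (x_t < x₀), β < 0 when right of it, and β = 0 for an upright
head or a circle (the degenerate-rotation convention). Reflecting a contour
across the vertical line through the center negates β exactly.

Half-plane cuts are strict: a pixel exactly on a cut line is discarded.
Every cut is anchored to the apex *direction* (the unit vector from the
center toward the apex), not to the sign of a slope-intercept expression,
because the latter flips with the y-direction convention and becomes
ambiguous for vertical cut lines. A consequence worth knowing: when a cut
line falls exactly on a pixel-row boundary (which happens when every
geometric quantity is an exact integer), the inclusion of that one row is
decided by sub-pixel fitting error. This is a measure-zero configuration;
the test suite and the phantom suite use generic sub-pixel geometry.

## Raw-to-grayscale transform

Frames are validated against the sensor range [−20, 100] °C at load; any
violation is rejected with the offending pixel coordinate. The grayscale
transform maps the frame minimum to 0 and maximum to 255 with floor
rounding (truncation), matching the integer-cast behavior of common imaging
stacks; any consistent rounding rule would do, and the monotonicity and
affine-invariance properties are tested. Constant frames are rejected
rather than mapped to zeros: with no head/background contrast the
downstream ellipse fit is meaningless.

On-disk raw formats are CSV (comma-separated floats, one image row per
line, no header), NumPy `.npy`, and single-channel 16-bit TIFF with an
affine decode `°C = value·scale + offset` declared by the caller. Masks are
8-bit single-channel PNGs holding exactly {0, 255}.

## Thresholding

Otsu's threshold is computed by evaluating the weighted within-class
variance of all 256 candidate splits via cumulative moments and taking the
first minimizer (ties break toward the smaller threshold). Minimizing
within-class variance is algebraically equivalent to the more common
between-class maximization; the within-class form is what the brute-force
oracle in the tests checks, split by split.

The result also carries a *separability* score η ∈ [0, 1], the
between-class share of the total variance. The pipeline rejects frames with
η < 0.75 as head-free: a head against a uniform background scores η close
to 1, while a frame of pure sensor noise scores about 0.65 (the Gaussian
value 2/π plus discretization effects). Without this guard, thresholding a
noise-only frame keeps roughly half its pixels, which percolate into one
giant 8-connected component and can yield a spurious ellipse. The guard is
deliberately coarse — it distinguishes "there is a foreground" from "there
is not", nothing finer.

After the contrast stretch and binarization, the largest 8-connected
component is kept (ties broken by the smallest top-left bounding-box
corner, row-major). This suppresses hands and other warm objects, which
become separate blobs once the background is removed. Interior holes are
then filled: glasses lenses and breathing masks are colder than skin (their
emissivity differs), fall below the Otsu threshold, and would otherwise
punch holes in the head mask. Unfilled holes harm twice — the erosion+XOR
contour would include the hole rims, dragging the ellipse fit inward, and
the glasses-mode landmark search would have no lens pixels to find inside
the face region.

The contour is the inner one-pixel boundary, `mask XOR erode(mask)` with a
3×3 square structuring element and zero padding at the frame edge (a head
touching the edge still yields boundary points there). Because the *inner*
boundary's pixel centers sit about half a pixel inside the continuous head
outline, fitted semi-axes are biased small by a comparable amount; this is
visible but harmless at the 30-pixel head scale used here.

## Ellipse fitting and geometry

The contour is fitted with the ellipse-specific direct least-squares
method: minimize the algebraic residual of the conic subject to
`4AC − B² = 1`, in the numerically stable split-design (3×3 eigenproblem)
formulation, with coordinates centered and scaled for conditioning and the
conic mapped back afterwards. The constraint guarantees an ellipse whenever
any ellipse fits. Conic coefficients are stored normalized (`4AC − B² = 1`,
`A + C > 0`), resolving the scale ambiguity.

Geometry is recovered canonically: the center solves the gradient system;
the semi-axes are `√(−F₀/λᵢ)` with `λᵢ` the eigenvalues of the quadratic
part and `F₀` the conic value at the center; the focal distance satisfies
`L² = R_max² − R_min²` (asserted to 1e−9 relative); the apex and
left-minor-axis endpoints come from the parametric form and are checked to
lie on the conic to 1e−6. The normalizing factor `K = −F₀` equals
`R_max·R_min/2` under the fixed normalization and is reported for
completeness.

Noiseless generate-and-refit is exact to 1e−6 in all five parameters. With
0.5-pixel coordinate noise on a 160-point head-geometry contour, recovery
is within 0.5 px in center/axes and 1° in β. The orientation tolerance is a
conditioning statement, not an implementation one: its uncertainty scales
like σ/((R_max − R_min)·√n), so near-circular contours have no
well-conditioned orientation and are excluded by construction (head aspect
ratios run ~0.53–0.78 here).

## Landmark detection

Which pixels to cluster is decided as follows: the extreme-temperature
decile (configurable `quantile`, default 0.10) of the upper-half face
region, as *candidate coordinates* for 2-means. Clustering coordinates (not
intensities) is what yields two spatial eye locations. Equal-valued pixel
groups are admitted from the extreme end while the running total stays
within the decile cap, so a uniform region — which has no distinct extreme —
raises an error instead of returning noise.

Mode matters: without glasses the *hottest* stretched intensities are
selected (eyes and inner canthi are the warmest facial features); with
glasses the *coldest raw temperatures* inside the face region are selected.
Raw temperatures are used in glasses mode because the contrast stretch
clamps sub-threshold lens pixels to zero and destroys their ordering.

2-means runs Lloyd's iteration under the Euclidean metric from
ellipse-derived seeds: offsets of ±R_min/2 across and R_max/2 along the
major axis from the center. A literal evaluation of that offset points into
the lower image half under the raster convention, so the major-axis
component is reflected across the center whenever the seed would land in
the discarded half. Convergence is declared when both centroid shifts fall
below 0.5 px (or at 100 iterations); on the phantom suite the seeded
initialization converges in ≤ 10 iterations. An emptied cluster is
re-seeded at the candidate farthest from the surviving center and logged,
never silently dropped. Output centers are canonically ordered left/right.

## Forehead cut and temperature

The midpoint of the two detected centers is shifted toward the apex by
`shift_fraction` (default 0.20) of the midpoint-to-apex distance, along the
midpoint→apex segment. (When the detected centers are symmetric this
coincides with measuring along the major axis; with asymmetric detections
the segment direction is used.) The forehead is the part of the upper
half-ellipse strictly on the apex side of the line through the shifted
midpoint parallel to the minor axis. A shifted midpoint beyond the apex
yields an empty region and a diagnostic error rather than a silently
flipped cut.

The mean forehead temperature is the exact per-pixel average of the raw
temperatures under the final mask (the mask weighting `P_mask/255` is the
identity for a {0, 255} mask); the pixel count `w ≥ 1` is enforced and
reported.

## The phantom generator

The generator renders what the pipeline assumes: a cool uniform background
(25 °C) behind a warm elliptical head, on a 120×140-pixel grid matching a
low-resolution thermal camera. Defaults: face 34 °C, eyes 36.5 °C (4-px
disks), lenses 28 °C (5-px disks), i.i.d. Gaussian sensor noise of 0.2 °C
(the order of a microbolometer noise floor), head semi-axes 30×20 px,
rotations limited to ±60°. Eye/lens disks sit at the half-semi-axis
positions — the same geometry the landmark seeds assume. Occluders (a 29 °C
breathing-mask disk over the mouth/chin, 31 °C beard patches around the
jaw) are stamped interior to the ellipse, as face-borne objects are.

The face carries a linear axial warmth gradient (default 2 °C
chin-to-forehead span): living skin is warmest toward the forehead. This
matters for the glasses-mode negative control. With a perfectly isothermal
face, the "hottest decile" under an inverted glasses flag is pure noise
scatter, and the left/right centroids of uniform scatter over a half-ellipse
sit at ~(4R_min/3π, 4R_max/3π) from the center — numerically almost the
half-semi-axis points where the lenses are. An isothermal face therefore
cannot demonstrate that the mode switch matters; a weak axial gradient is
both more realistic and makes the inverted-mode detector land at the apex,
~10 px from the lenses.

Ground truth is analytic and uses the same geometric rule the method
targets: the forehead truth mask is the head-ellipse region strictly above
the line through the 20%-shifted midpoint of the *true* eye centers,
parallel to the minor axis. End-to-end IoU therefore measures detection
robustness (thresholding, fitting, clustering under noise, rotation and
occlusion), not disagreement about the rule itself. The "programmed
forehead temperature" of a phantom is the noise-free rendered field
averaged under the truth mask — rendered, not pure skin, because disks
centered at the half-semi-axis positions geometrically always graze the
20% cut line, so thin eye/lens slivers legitimately belong to the region.

What the phantoms do **not** model: hair and ears (real heads are not clean
ellipses), emissivity spectra of clothing and skin, spatially correlated
sensor noise and fixed-pattern artifacts, camera point-spread blur at the
head boundary, perspective effects, and multi-person scenes. Passing the
suite therefore shows the geometric pipeline is correct and robust to the
modeled perturbations; it does not by itself certify accuracy on real
camera data, where boundary blur and non-elliptical silhouettes are the
dominant additional error sources.

## Problem sizes and evaluation

The standard evaluation suite is 200 phantoms drawn reproducibly from a
master seed: rotation uniform in [−20°, 20°], glasses with probability 0.5,
occluders with probability 0.3, semi-axes jittered in [27, 32]×[17, 21] px,
centers jittered ±4 px, noise sd 0.2 °C. Per-frame failures are recorded
with their stage name, counted, and excluded from the mean IoU — they are
never averaged in and never abort a batch. On this suite the pipeline's
mean IoU against the analytic truth is ≈ 0.98 with zero failures (see
`scripts/acceptance.py`); the residual gap to 1.0 is dominated by one-row
quantization where the cut line crosses pixel rows, which costs up to
~0.1 IoU on the ~250-pixel forehead region of a single frame.

## Known limitations

- Exactly one head is assumed after the largest-component step.
- The method needs head/background thermal contrast; matched backgrounds
  are rejected by the separability guard rather than segmented.
- The forehead region is defined geometrically (ellipse + cut), not
  anatomically; systematic offsets against an anatomical ground truth are
  absorbed into the 20% shift, which is configurable.
- β near ±90° is handled by the implicit line form, but the clockwise sign
  convention has a discontinuity there (a vertical-major-axis tie is broken
  toward positive β).
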
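"""Eye/lens landmark detection: initialization, candidates, 2-means."""

import itertools
import math

import numpy as np
import pytest

from thermoface import (
    BinaryMask,
    GrayFrame,
    ThermalFrame,
    detect_eye_regions,
    geometry_from_params,
    init_clusters,
    kmeans2,
    select_candidates,
)
from thermoface.errors import InsufficientCandidatesError
from thermoface.forehead import run_pipeline
from thermoface.preprocess import PointSet


class TestInitClusters:
    def test_upright_ellipse_seeds_in_upper_half(self):
        # literal half-semi-axis rule points down the image; the reflection
        # rule flips it into the retained (upper) half: (60,45), (80,45)
        geom = geometry_from_params((70, 60), 30, 20, 0.0)
        pair = init_clusters(geom)
        assert pair.c1 == pytest.approx((60.0, 45.0), abs=1e-9)
        assert pair.c2 == pytest.approx((80.0, 45.0), abs=1e-9)

    def test_seeds_mirror_across_vertical_center_line(self):
        geom = geometry_from_params((70, 60), 30, 20, 0.0)
        pair = init_clusters(geom)
        assert pair.c1[0] + pair.c2[0] == pytest.approx(2 * 70.0, abs=1e-9)
        assert pair.c1[1] == pytest.approx(pair.c2[1], abs=1e-9)

    def test_90_degree_rotation_mirrors_across_horizontal(self):
        geom = geometry_from_params((70, 60), 30, 20, math.pi / 2)
        pair = init_clusters(geom)
        assert pair.c1[1] + pair.c2[1] == pytest.approx(2 * 60.0, abs=1e-9)
        assert pair.c1[0] == pytest.approx(pair.c2[0], abs=1e-9)

    @pytest.mark.parametrize("beta_deg", [-40, -15, 0, 15, 40])
    def test_seeds_always_in_kept_half(self, beta_deg):
        from thermoface.ellipse_geom import minor_axis_line

        geom = geometry_from_params((70, 60), 30, 20, math.radians(beta_deg))
        line = minor_axis_line(geom)
        pair = init_clusters(geom)
        for c in (pair.c1, pair.c2):
            assert line.keep_sign * line.signed_distance(*c) > 0


class TestSelectCandidates:
    def _region(self, shape=(20, 20), n_face=200):
        fg = np.zeros(shape, dtype=bool)
        fg.ravel()[:n_face] = True
        return fg

    def test_top_decile_picks_only_distinct_hot_group(self):
        # 200-px region: 10 px at 255 over a face at 150; cap is 20 px but
        # only the distinct hottest group (10 px) qualifies
        fg = self._region()
        vals = np.zeros((20, 20), dtype=np.uint8)
        vals[fg] = 150
        hot = np.zeros_like(fg)
        hot.ravel()[:10] = True
        vals[hot] = 255
        raw = ThermalFrame(np.full((20, 20), 30.0))
        pts = select_candidates(GrayFrame(vals), raw, BinaryMask.from_bool(fg),
                                has_glasses=False, quantile=0.10)
        assert len(pts) == 10
        assert vals[pts.y, pts.x].min() == 255

    def test_glasses_candidates_confined_to_lenses(self, glasses_phantom):
        from thermoface import (
            binarize,
            cut_halfplane,
            fill_holes,
            largest_component,
            minor_axis_line,
            otsu_threshold,
            stretch_threshold,
            to_grayscale,
        )

        spec, frame, truth = glasses_phantom
        gray = to_grayscale(frame)
        m = otsu_threshold(gray).threshold
        stretched = stretch_threshold(gray, m)
        head = fill_holes(largest_component(binarize(stretched)))
        upper = cut_halfplane(head, minor_axis_line(truth.geometry))
        pts = select_candidates(stretched, frame, upper, has_glasses=True)
        lens_centers = np.array([truth.eye_centers.c1, truth.eye_centers.c2])
        d = np.min(
            np.linalg.norm(
                pts.points[:, None, :] - lens_centers[None, :, :], axis=2
            ),
            axis=1,
        )
        assert (d <= spec.lens_radius_px + 0.5).all()

    def test_uniform_region_has_no_distinct_extreme(self):
        fg = self._region()
        vals = np.zeros((20, 20), dtype=np.uint8)
        vals[fg] = 150
        raw = ThermalFrame(np.full((20, 20), 30.0))
        with pytest.raises(InsufficientCandidatesError):
            select_candidates(GrayFrame(vals), raw, BinaryMask.from_bool(fg),
                              has_glasses=False)


def brute_force_two_means(points: np.ndarray) -> float:
    """Minimum 2-cluster within-SSE over all bipartitions (tiny n only)."""
    best = np.inf
    n = len(points)
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        sse = 0.0
        for k in (0, 1):
            members = points[assign == k]
            if len(members) == 0:
                break
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        else:
            best = min(best, sse)
    return best


class TestKMeans:
    def test_two_blobs_reach_globally_optimal_partition(self, rng):
        blob1 = rng.normal((55, 45), 0.8, (6, 2))
        blob2 = rng.normal((85, 45), 0.8, (6, 2))
        rounded = np.unique(np.round(np.vstack([blob1, blob2])).astype(int),
                            axis=0)
        pts = PointSet(rounded)
        blob1 = rounded[rounded[:, 0] < 70].astype(float)
        blob2 = rounded[rounded[:, 0] >= 70].astype(float)
        init = init_clusters(geometry_from_params((70, 60), 30, 20, 0.0))
        pair = kmeans2(pts, init)
        coords = pts.points.astype(float)
        # compare attained SSE with the exhaustive bipartition oracle
        d = np.linalg.norm(coords[:, None, :] - pair.as_array()[None], axis=2)
        assign = d.argmin(axis=1)
        sse = sum(
            ((coords[assign == k] - coords[assign == k].mean(0)) ** 2).sum()
            for k in (0, 1)
        )
        assert sse == pytest.approx(brute_force_two_means(coords), rel=1e-6)
        assert np.linalg.norm(np.array(pair.c1) - blob1.mean(0)) < 1.0
        assert np.linalg.norm(np.array(pair.c2) - blob2.mean(0)) < 1.0

    def test_tight_candidates_trigger_reseed_and_stay_finite(self):
        # both seeds' members collapse onto one side: the far cluster
        # empties and is re-seeded rather than dropped
        pts = PointSet(np.array([[10, 10], [10, 11]]))
        from thermoface.landmarks import ClusterPair

        pair = kmeans2(pts, ClusterPair((10.0, 10.5), (40.0, 40.0)))
        assert np.isfinite(pair.as_array()).all()
        assert pair.member_counts is not None

    def test_mirror_symmetric_input_gives_mirror_centers(self):
        pts = np.array(
            [[60, 45], [61, 44], [59, 46], [80, 45], [79, 44], [81, 46]]
        )
        init = init_clusters(geometry_from_params((70, 60), 30, 20, 0.0))
        pair = kmeans2(PointSet(pts), init)
        assert pair.c1[0] + pair.c2[0] == pytest.approx(140.0, abs=1e-9)
        assert pair.c1[1] == pytest.approx(pair.c2[1], abs=1e-9)

    def test_result_invariant_to_candidate_ordering(self, rng):
        pts = np.vstack(
            [rng.normal((55, 45), 1.0, (8, 2)), rng.normal((85, 45), 1.0, (8, 2))]
        )
        pts = np.round(pts).astype(int)
        pts = np.unique(pts, axis=0)
        init = init_clusters(geometry_from_params((70, 60), 30, 20, 0.0))
        a = kmeans2(PointSet(pts), init)
        b = kmeans2(PointSet(pts[::-1].copy()), init)
        assert a.c1 == pytest.approx(b.c1, abs=1e-9)
        assert a.c2 == pytest.approx(b.c2, abs=1e-9)


class TestDetectEyeRegions:
    def test_eye_centers_recovered_within_3px(self, eye_phantom):
        spec, frame, truth = eye_phantom
        res = run_pipeline(frame, has_glasses=False)
        for det, true in [(res.eyes.c1, truth.eye_centers.c1),
                          (res.eyes.c2, truth.eye_centers.c2)]:
            assert np.linalg.norm(np.array(det) - np.array(true)) < 3.0

    def test_lens_centers_recovered_within_3px(self, glasses_phantom):
        spec, frame, truth = glasses_phantom
        res = run_pipeline(frame, has_glasses=True)
        for det, true in [(res.eyes.c1, truth.eye_centers.c1),
                          (res.eyes.c2, truth.eye_centers.c2)]:
            assert np.linalg.norm(np.array(det) - np.array(true)) < 3.0

    def test_inverted_glasses_flag_lands_off_lens(self, glasses_phantom):
        # negative control: searching for hot spots on a glasses face finds
        # warm forehead skin, far from the cold lenses
        spec, frame, truth = glasses_phantom
        res = run_pipeline(frame, has_glasses=False)
        for det in (res.eyes.c1, res.eyes.c2):
            d = min(
                np.linalg.norm(np.array(det) - np.array(truth.eye_centers.c1)),
                np.linalg.norm(np.array(det) - np.array(truth.eye_centers.c2)),
            )
            assert d > 5.0

    def test_converges_in_few_iterations_from_ellipse_seeds(self, eye_phantom):
        _, frame, _ = eye_phantom
        res = run_pipeline(frame, has_glasses=False)
        assert res.eyes.n_iterations <= 10

    def test_horizontal_mirror_mirrors_centers(self, eye_phantom):
        spec, frame, truth = eye_phantom
        res = run_pipeline(frame, has_glasses=False)
        mirrored = ThermalFrame(frame.values[:, ::-1].copy())
        res_m = run_pipeline(mirrored, has_glasses=False)
        width = frame.values.shape[1]
        # mirror of c2 becomes the new c1 after canonical reordering
        assert res_m.eyes.c1[0] == pytest.approx(
            width - 1 - res.eyes.c2[0], abs=1.0
        )
        assert res_m.eyes.c2[0] == pytest.approx(
            width - 1 - res.eyes.c1[0], abs=1.0
        )
        assert res_m.eyes.c1[1] == pytest.approx(res.eyes.c2[1], abs=1.0)
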
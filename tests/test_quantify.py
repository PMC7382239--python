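import math

import numpy as np
import pytest

import mtconfine as mc
from mtconfine.quantify import (diagonal_square, face_projection, fixtures,
                                isotropic, nematic_tensor_image,
                                orthogonal_grid, parallel_array,
                                render_image, s2_order)


def brute_force_s2(segments):
    """Independent oracle: eigen-decomposition of the weighted 2D
    nematic tensor; its eigenvalue difference equals S2 and its
    principal axis equals ThetaS2."""
    segments = np.asarray(segments, float)
    q = np.zeros((2, 2))
    wsum = 0.0
    for x0, y0, x1, y1 in segments:
        dx, dy = x1 - x0, y1 - y0
        w = math.hypot(dx, dy)
        u = np.array([dx, dy]) / w
        q += w * np.outer(u, u)
        wsum += w
    q /= wsum
    evals, evecs = np.linalg.eigh(q)
    s2 = evals[1] - evals[0]
    v = evecs[:, 1]
    ang = math.degrees(math.atan2(v[1], v[0]))
    if ang <= -90:
        ang += 180
    elif ang > 90:
        ang -= 180
    return s2, ang


def random_segments(rng, n):
    seg = rng.uniform(-5, 5, size=(n, 4))
    return seg[np.hypot(seg[:, 2] - seg[:, 0],
                        seg[:, 3] - seg[:, 1]) > 1e-6]


class TestS2Order:
    def test_perfect_order(self):
        r = s2_order(parallel_array(30.0, 50))
        assert r.s2 == pytest.approx(1.0, abs=1e-12)
        assert r.theta_s2 == pytest.approx(30.0, abs=1e-9)

    def test_orthogonal_pair_cancels(self):
        segs = np.array([[0, 0, 1, 0], [0, 0, 0, 1.0]])
        assert s2_order(segs).s2 == pytest.approx(0.0, abs=1e-15)

    def test_two_one_split(self):
        # three unit segments at 0, 0, 90: <cos2t> = (1+1-1)/3 = 1/3
        segs = np.array([[0, 0, 1, 0], [2, 0, 3, 0], [0, 1, 0, 2.0]])
        r = s2_order(segs)
        assert r.s2 == pytest.approx(1 / 3, abs=1e-12)
        assert r.theta_s2 == pytest.approx(0.0, abs=1e-9)

    def test_empty_and_zero_weight_flagged(self):
        r = s2_order(np.empty((0, 4)))
        assert not r.defined and r.theta_s2 is None

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            segs = random_segments(rng, rng.integers(2, 40))
            r = s2_order(segs)
            s2_ref, ang_ref = brute_force_s2(segs)
            assert r.s2 == pytest.approx(s2_ref, abs=1e-12)
            if r.s2 > 1e-6:
                d = abs(r.theta_s2 - ang_ref) % 180
                assert min(d, 180 - d) < 1e-6

    def test_invariances(self):
        rng = np.random.default_rng(21)
        segs = random_segments(rng, 30)
        base = s2_order(segs)
        # ordering
        perm = segs[rng.permutation(len(segs))]
        assert s2_order(perm).s2 == pytest.approx(base.s2, abs=1e-12)
        # per-segment orientation flips
        flip = segs.copy()
        idx = rng.random(len(segs)) < 0.5
        flip[idx] = flip[idx][:, [2, 3, 0, 1]]
        assert s2_order(flip).s2 == pytest.approx(base.s2, abs=1e-12)
        # uniform weight rescaling
        assert s2_order(segs * 3.7).s2 == pytest.approx(base.s2, abs=1e-12)
        # global rotation rotates ThetaS2 by the same amount
        phi = math.radians(25.0)
        rot = np.array([[math.cos(phi), -math.sin(phi)],
                        [math.sin(phi), math.cos(phi)]])
        a = segs[:, :2] @ rot.T
        b = segs[:, 2:] @ rot.T
        rot_res = s2_order(np.hstack([a, b]))
        assert rot_res.s2 == pytest.approx(base.s2, abs=1e-12)
        d = (rot_res.theta_s2 - base.theta_s2 - 25.0) % 180
        assert min(d, 180 - d) < 1e-9


class TestFixtures:
    def test_dispatcher_and_parallel(self):
        segs = fixtures("parallel_array", seed=1, theta0=0.0, n=50)
        assert s2_order(segs).s2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_grid_exact_zero(self):
        for n in (1, 7, 64):
            assert s2_order(orthogonal_grid(n)).s2 == 0.0

    def test_isotropic_large_n(self):
        # E[S2] ~ sqrt(pi/(4n)) ~ 0.0089 at n = 10,000
        segs = isotropic(10_000, rng=np.random.default_rng(2))
        assert s2_order(segs).s2 < 0.03

    def test_isotropic_expectation_matches_theory(self):
        n = 400
        vals = [s2_order(isotropic(n, rng=np.random.default_rng(s))).s2
                for s in range(60)]
        expected = math.sqrt(math.pi / (4 * n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)

    def test_diagonal_square_bias(self):
        assert s2_order(diagonal_square(40)).s2 == pytest.approx(0, abs=1e-12)
        r = s2_order(diagonal_square(40, bias=3.0))
        assert r.s2 == pytest.approx(0.5, abs=1e-12)
        assert r.theta_s2 == pytest.approx(45.0, abs=1e-9)

    def test_unknown_fixture(self):
        with pytest.raises(ValueError):
            fixtures("nope")


class TestFaceProjection:
    def test_shell_selects_near_face(self, rect_box):
        top, bottom = rect_box.analysis_faces()
        poly = [np.array([[0, 0, 7.4], [0.2, 0, 7.4]])]
        assert len(face_projection(poly, top, 0.5)) == 1
        assert len(face_projection(poly, bottom, 0.5)) == 0

    def test_perpendicular_element_zero_weight(self, rect_box):
        top, _ = rect_box.analysis_faces()
        poly = [np.array([[0, 0, 7.0], [0, 0, 7.2]])]
        assert len(face_projection(poly, top, 0.5)) == 0

    def test_inclined_element_cosine_weight(self, rect_box):
        top, _ = rect_box.analysis_faces()
        ell = 0.2
        c = ell / math.sqrt(2)
        poly = [np.array([[0, 0, 7.3], [c, 0, 7.3 + c]])]
        segs = face_projection(poly, top, 0.5)
        w = np.hypot(segs[:, 2] - segs[:, 0], segs[:, 3] - segs[:, 1]).sum()
        assert w == pytest.approx(ell / math.sqrt(2), abs=1e-12)

    def test_slab_clipping_partial_element(self, rect_box):
        top, _ = rect_box.analysis_faces()
        # vertical chord entering the slab [7.0, 7.5] halfway: only the
        # inner half contributes, but projects to zero length; tilt it
        poly = [np.array([[0, 0, 6.6], [0.8, 0, 7.4]])]
        segs = face_projection(poly, top, 0.5)
        w = np.hypot(segs[:, 2] - segs[:, 0], segs[:, 3] - segs[:, 1]).sum()
        assert w == pytest.approx(0.4, abs=1e-9)  # x-extent inside slab

    def test_sphere_cap_selection(self, sphere10):
        top, bottom = sphere10.analysis_faces()
        near_top = [np.array([[0, 0, 9.8], [0.2, 0, 9.8]])]
        assert len(face_projection(near_top, top, 0.5)) == 1
        assert len(face_projection(near_top, bottom, 0.5)) == 0
        centre = [np.array([[0, 0, 0], [0.2, 0, 0]])]
        assert len(face_projection(centre, top, 0.5)) == 0

    def test_empty_state(self, rect_box):
        top, _ = rect_box.analysis_faces()
        assert face_projection([], top, 0.5).shape == (0, 4)


class TestImagePath:
    def test_horizontal_stripes(self):
        y = np.arange(96)[:, None]
        img = np.sin(2 * np.pi * y / 8.0) * np.ones((96, 96))
        r = nematic_tensor_image(img)
        assert abs(r.angle) < 1e-6
        assert r.anisotropy > 0.999

    def test_noise_isotropic(self):
        vals = [nematic_tensor_image(
            np.random.default_rng(s).random((256, 256))).anisotropy
            for s in range(20)]
        assert max(vals) < 0.05

    def test_constant_image_flagged(self):
        r = nematic_tensor_image(np.ones((32, 32)))
        assert not r.defined

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(30)
        img = render_image(segments=parallel_array(30.0, 40, length=3.0,
                                                   rng=rng))
        a = nematic_tensor_image(img)
        b = nematic_tensor_image(2.5 * img + 7.0)
        assert b.anisotropy == pytest.approx(a.anisotropy, abs=1e-9)
        assert b.angle == pytest.approx(a.angle, abs=1e-9)

    def test_roi_restricts_pixels(self):
        y = np.arange(64)[:, None]
        img = np.sin(2 * np.pi * y / 8.0) * np.ones((64, 64))
        roi = np.array([[5, 5], [5, 30], [30, 30], [30, 5]])
        r = nematic_tensor_image(img, roi=roi)
        assert r.defined and abs(r.angle) < 1e-6
        with pytest.raises(ValueError):
            nematic_tensor_image(img, roi=np.array([[0, 0], [0, 2], [2, 0]]))


class TestRenderConsistency:
    def test_single_mt_along_x(self, rect_box):
        top, _ = rect_box.analysis_faces()
        xs = np.linspace(-5, 5, 51)
        poly = [np.column_stack([xs, np.zeros(51), np.full(51, 7.3)])]
        img = render_image(poly, top)
        r = nematic_tensor_image(img)
        assert abs(r.angle) < 2.0

    @pytest.mark.parametrize("theta0", [0.0, 30.0, 60.0])
    def test_parallel_array_cross_path(self, theta0):
        segs = parallel_array(theta0, 40, length=12.0,
                              rng=np.random.default_rng(31))
        seg_res = s2_order(segs)
        img = render_image(segments=segs)
        img_res = nematic_tensor_image(img)
        d = abs(img_res.angle - seg_res.theta_s2) % 180
        assert min(d, 180 - d) < 3.0
        assert seg_res.s2 > 0.9 and img_res.anisotropy > 0.9

    def test_empty_state_zero_image(self, rect_box):
        top, _ = rect_box.analysis_faces()
        img = render_image([], top)
        assert img.sum() == 0.0

    def test_poisson_noise_deterministic(self):
        segs = parallel_array(0.0, 10, rng=np.random.default_rng(5))
        a = render_image(segments=segs, noise=50.0,
                         rng=np.random.default_rng(7))
        b = render_image(segments=segs, noise=50.0,
                         rng=np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestFaceOrderParameters:
    def test_combined_means(self, rect_box):
        # aligned filaments near both faces: combined S2 ~ 1, theta ~ 0
        polys = [np.array([[x, y, z], [x + 3, y, z]])
                 for x in (-5, 0) for y in (-3, 3) for z in (7.2, -7.2)]
        fp = mc.face_order_parameters(polys, rect_box)
        assert fp.top.defined and fp.bottom.defined
        assert fp.s2_mean == pytest.approx(1.0, abs=1e-9)
        assert abs(fp.theta_mean) < 1e-6
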
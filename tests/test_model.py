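"""Segmentation model: elementary operators and the alternating loop."""

import numpy as np
import pytest

from powerseg import (
    ModelParams,
    RegionCenters,
    curvature_term,
    energy,
    generalized_sample_mean,
    init_membership,
    jaccard,
    membership_closed_form,
    membership_time_step,
    normalize_image,
    regularize_membership,
    robust_weights,
    segment,
    update_centers,
)
from powerseg.model import _tv


class TestNormalizeImage:
    def test_affine_endpoints(self):
        raw = np.array([[0.0, 100.0], [200.0, 255.0]])
        out = normalize_image(raw)
        assert out[0, 0] == 0.0 and out[1, 1] == 1.0

    def test_idempotent_on_full_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (8, 8))
        img[0, 0], img[-1, -1] = 0.0, 1.0
        assert np.allclose(normalize_image(img), img)

    def test_constant_image_degenerates_to_half(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out = normalize_image(np.full((4, 4), 7.0))
        assert np.all(out == 0.5)

    def test_rejects_non_finite(self):
        bad = np.ones((3, 3))
        bad[1, 1] = np.nan
        with pytest.raises(ValueError):
            normalize_image(bad)


class TestRobustWeights:
    def test_unit_grid_at_p_one(self):
        img = np.random.default_rng(1).uniform(0, 1, (5, 5))
        assert np.allclose(robust_weights(img, 0.4, p=1.0), 1.0)

    def test_inverse_distance_at_half(self):
        img = np.full((2, 2), 0.7)
        # (u-c)^2 = 0.04 -> weight 0.04^(-1/2) = 5
        assert robust_weights(img, 0.5, p=0.5)[0, 0] == pytest.approx(5.0)

    def test_eps_guard(self):
        img = np.full((2, 2), 0.5)
        w = robust_weights(img, 0.5, p=0.5, eps=1e-8)
        assert np.allclose(w, 1e4)


class TestUpdateCenters:
    def test_crisp_region_plain_means_at_p_one(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (16, 16))
        z = np.zeros_like(img)
        z[:8] = 1.0
        params = ModelParams(p=1.0)
        c = update_centers(img, z, RegionCenters(0.7, 0.3), params)
        assert c.c1 == pytest.approx(img[:8].mean(), abs=1e-12)
        assert c.c2 == pytest.approx(img[8:].mean(), abs=1e-12)

    def test_constant_region_center_is_its_value(self):
        img = np.full((8, 8), 0.6)
        z = np.ones_like(img)
        c = update_centers(img, z, RegionCenters(0.9, 0.1), ModelParams())
        assert c.c1 == pytest.approx(0.6, abs=1e-12)

    def test_full_membership_fixed_point_is_generalized_mean(self):
        # with z = 1 everywhere, iterating the c1 update reproduces the
        # robust location estimate of the whole image
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (12, 12))
        params = ModelParams(p=0.6)
        z = np.ones_like(img)
        c = RegionCenters(float(img.mean()), 0.0)
        for _ in range(200):
            c = RegionCenters(
                update_centers(img, z, c, params).c1, 0.0)
        oracle = generalized_sample_mean(img.ravel(), 0.6).value
        assert c.c1 == pytest.approx(oracle, abs=1e-6)

    def test_empty_region_keeps_previous_center(self):
        img = np.random.default_rng(4).uniform(0, 1, (6, 6))
        z = np.zeros_like(img)
        with pytest.warns(RuntimeWarning, match="empty foreground"):
            c = update_centers(img, z, RegionCenters(0.42, 0.1), ModelParams())
        assert c.c1 == 0.42


class TestClosedFormMembership:
    def test_symmetry_gives_half(self):
        img = np.full((4, 4), 0.5)
        z = membership_closed_form(img, RegionCenters(0.3, 0.7), ModelParams())
        assert np.allclose(z, 0.5, atol=1e-12)

    def test_perfect_foreground_limit(self):
        img = np.full((4, 4), 0.8)
        z = membership_closed_form(img, RegionCenters(0.8, 0.2), ModelParams())
        assert np.all(z > 1 - 1e-3)

    def test_hand_value(self):
        # d1 = 0.01, d2 = 0.04, p = 0.5, m = 2 -> z = 0.2/(0.1+0.2) = 2/3
        img = np.full((2, 2), 0.5)
        z = membership_closed_form(img, RegionCenters(0.4, 0.3), ModelParams())
        assert np.allclose(z, 2.0 / 3.0, atol=1e-12)

    @pytest.mark.parametrize("p", [0.5, 0.8, 1.0])
    def test_m2_identity_with_power_ratio(self, p):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (17, 13))
        c1, c2 = rng.uniform(0, 1, 2)
        params = ModelParams(p=p)
        z = membership_closed_form(img, RegionCenters(c1, c2), params)
        d1 = np.maximum((img - c1) ** 2, params.eps)
        d2 = np.maximum((img - c2) ** 2, params.eps)
        assert np.allclose(z, d2**p / (d1**p + d2**p), atol=1e-12)
        assert z.min() >= 0 and z.max() <= 1


class TestCurvature:
    def test_constant_field_zero(self):
        assert np.allclose(curvature_term(np.full((10, 10), 0.3)), 0.0)

    def test_planar_ramp_zero_interior(self):
        n = 32
        z = np.tile(np.arange(n) / n, (n, 1))
        k = curvature_term(z)
        assert np.abs(k[2:-2, 2:-2]).max() < 1e-10

    def test_radial_cone_curvature_one_over_r(self):
        n = 201
        rr, cc = np.mgrid[0:n, 0:n]
        r = np.sqrt((rr - 100.0) ** 2 + (cc - 100.0) ** 2)
        k = curvature_term(r)
        sel = (r >= 5) & (r <= 50)
        assert np.max(np.abs(k[sel] * r[sel] - 1.0)) < 0.10


class TestTimeStep:
    def test_zero_dt_is_identity(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 1, (9, 9))
        z = rng.uniform(0, 1, (9, 9))
        params = ModelParams(dt=1e-300)
        out = membership_time_step(z, img, RegionCenters(0.8, 0.2), params)
        assert np.allclose(out, z, atol=1e-12)

    def test_closed_form_is_stationary_without_curvature(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 1, (11, 11))
        params = ModelParams(mu=0.0, dt=0.5)
        centers = RegionCenters(0.75, 0.25)
        z = membership_closed_form(img, centers, params)
        out = membership_time_step(z, img, centers, params)
        assert np.allclose(out, z, atol=1e-12)

    def test_update_sign_toward_closer_center(self):
        img = np.full((6, 6), 0.7)  # closer to c1=0.8 than c2=0.2
        z = np.full((6, 6), 0.5)
        params = ModelParams(mu=0.0)
        out = membership_time_step(z, img, RegionCenters(0.8, 0.2), params)
        assert np.all(out > 0.5)

    def test_output_clipped_to_unit_interval(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 1, (15, 15))
        z = rng.uniform(0, 1, (15, 15))
        params = ModelParams(dt=10.0)  # deliberately huge step
        out = membership_time_step(z, img, RegionCenters(0.9, 0.1), params)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestRegularize:
    def test_sigma_zero_identity_and_constant_preserved(self):
        rng = np.random.default_rng(9)
        z = rng.uniform(0, 1, (8, 8))
        assert np.array_equal(regularize_membership(z, 0.0), z)
        const = np.full((8, 8), 0.4)
        assert np.allclose(regularize_membership(const, 3.0), 0.4)

    def test_impulse_mass_preserved_and_peak_lowered(self):
        z = np.zeros((41, 41))
        z[20, 20] = 1.0
        out = regularize_membership(z, 3.0)
        assert out[20, 20] < 1.0
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestEnergy:
    def test_half_membership_algebraic_value(self):
        rng = np.random.default_rng(10)
        img = rng.uniform(0, 1, (10, 10))
        params = ModelParams(mu=0.0)
        centers = RegionCenters(0.7, 0.3)
        z = np.full_like(img, 0.5)
        d1 = np.maximum((img - 0.7) ** 2, params.eps) ** params.p
        d2 = np.maximum((img - 0.3) ** 2, params.eps) ** params.p
        expected = 0.25 * float((d1 + d2).sum())
        assert energy(img, z, centers, params) == pytest.approx(expected, rel=1e-12)

    def test_perfect_crisp_fit_is_eps_scale(self, noiseless_disk):
        img, truth = noiseless_disk
        params = ModelParams(mu=0.0)
        e = energy(img, truth.astype(float), RegionCenters(0.8, 0.2), params)
        assert e <= 2 * img.size * params.eps**params.p

    def test_tv_of_disk_matches_circumference(self):
        rr, cc = np.mgrid[0:128, 0:128]
        disk = (((rr - 63.5) ** 2 + (cc - 63.5) ** 2) <= 400).astype(float)
        tv = _tv(disk, 1e-8)
        assert tv == pytest.approx(2 * np.pi * 20, rel=0.15)

    def test_convex_in_membership(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(0, 1, (16, 16))
        params = ModelParams()
        centers = RegionCenters(0.8, 0.2)
        for _ in range(30):
            z0 = rng.uniform(0, 1, img.shape)
            z1 = rng.uniform(0, 1, img.shape)
            t = rng.uniform(0.05, 0.95)
            lhs = energy(img, t * z0 + (1 - t) * z1, centers, params)
            rhs = t * energy(img, z0, centers, params) + (1 - t) * energy(
                img, z1, centers, params)
            assert lhs <= rhs + 1e-9


class TestInitMembership:
    def test_modes_and_determinism(self):
        assert np.all(init_membership((8, 8), "constant") == 0.5)
        disk = init_membership((64, 64), "disk")
        assert set(np.unique(disk)) == {0.0, 1.0}
        assert disk[32, 32] == 1.0 and disk[0, 0] == 0.0
        half = init_membership((8, 10), "half_plane")
        assert np.all(half[:, :5] == 1) and np.all(half[:, 5:] == 0)
        r1 = init_membership((16, 16), "random", seed=42)
        r2 = init_membership((16, 16), "random", seed=42)
        assert np.array_equal(r1, r2)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown init mode"):
            init_membership((8, 8), "spiral")


class TestSegment:
    def test_noiseless_exact_recovery_without_smoothing(self, noiseless_disk):
        img, truth = noiseless_disk
        res = segment(img, ModelParams(sigma=0.0))
        assert jaccard(res.mask, truth) == 1.0
        assert res.converged
        assert abs(res.centers.c1 - 0.8) < 1e-6 and abs(res.centers.c2 - 0.2) < 1e-6

    def test_noiseless_recovery_at_defaults(self, noiseless_disk):
        # sigma=3 smoothing of a crisp r=20 disk flips ~30 boundary pixels
        img, truth = noiseless_disk
        res = segment(img)
        assert jaccard(res.mask, truth) > 0.97

    def test_membership_in_unit_interval_and_trace_lengths(self, speckled_scene):
        img, truth = speckled_scene
        res = segment(img, ModelParams(max_iter=20, tol=1e-12),
                      ground_truth=truth)
        assert res.membership.min() >= 0 and res.membership.max() <= 1
        assert len(res.energy_trace) == res.iterations
        assert len(res.jaccard_trace) == res.iterations

    def test_membership_range_every_iteration(self, speckled_scene):
        img, _ = speckled_scene
        seen = []
        segment(img, ModelParams(max_iter=15, tol=1e-12),
                callback=lambda it, z, c: seen.append((z.min(), z.max())))
        assert seen and all(lo >= 0 and hi <= 1 for lo, hi in seen)

    def test_energy_trace_monotone_without_regularization(self, speckled_scene):
        img, _ = speckled_scene
        res = segment(img, ModelParams(sigma=0.0, mu=0.0))
        assert np.all(np.diff(res.energy_trace) <= 1e-10)

    def test_closed_form_coordinate_optimality(self, speckled_scene):
        # with mu=0 and frozen weights/centers the closed-form z cannot be
        # beaten by random perturbations of itself
        img, _ = speckled_scene
        params = ModelParams(mu=0.0)
        centers = RegionCenters(0.8, 0.2)
        z = membership_closed_form(img, centers, params)
        e0 = energy(img, z, centers, params)
        rng = np.random.default_rng(12)
        for _ in range(50):
            zp = np.clip(z + rng.normal(0, 0.05, z.shape), 0, 1)
            assert e0 <= energy(img, zp, centers, params)

    def test_init_mode_does_not_change_result(self, speckled_scene):
        img, _ = speckled_scene
        masks = [segment(img, init_mode=mode).mask
                 for mode in ("half_plane", "disk", "random", "constant")]
        for m in masks[1:]:
            assert np.array_equal(masks[0], m)

    def test_time_marching_runs_and_stays_bounded(self, noiseless_disk):
        img, truth = noiseless_disk
        params = ModelParams(solver="time_marching", sigma=0.0, mu=0.2,
                             max_iter=60, dt=0.25)
        res = segment(img, params, init=truth.astype(float))
        assert res.membership.min() >= 0 and res.membership.max() <= 1
        assert jaccard(res.mask, truth) > 0.95

    def test_constant_image_single_region_flag(self):
        with pytest.warns(RuntimeWarning):
            res = segment(np.full((8, 8), 0.5))
        assert res.degenerate and res.iterations == 0

    def test_rejects_unnormalized_image(self):
        with pytest.raises(ValueError, match="normalized"):
            segment(np.array([[0.0, 2.0], [1.0, 0.5]]))

    def test_nonconvergence_flag(self, speckled_scene):
        img, _ = speckled_scene
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = segment(img, ModelParams(max_iter=2, tol=1e-15))
        assert not res.converged and res.iterations == 2
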
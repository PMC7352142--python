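"""Similarity metrics, warping, field algebra and the three registrations."""

import numpy as np
import pytest

from cyclereg import (AffineTransform, DeformationField, ImageGrid,
                      RegistrationConfig, affine_register, average_fields,
                      compose_affine_field, demons_register, ffd_register,
                      field_from_affine, similarity, warp)


def constant_field(shape, dr, dc, spacing=(1.0, 1.0)):
    d = np.zeros(shape + (2,))
    d[:, :, 0] = dr
    d[:, :, 1] = dc
    return DeformationField(d, spacing)


class TestSimilarity:
    def test_ssd_zero_for_identical(self, rng):
        img = rng.random((20, 20))
        assert similarity(img, img, "SSD") == 0.0

    def test_ncc_minus_one_for_identical(self, rng):
        img = rng.random((20, 20))
        assert similarity(img, img, "NCC") == pytest.approx(-1.0)

    def test_mi_ranks_identical_below_independent(self, rng):
        a = rng.random((64, 64))
        b = rng.random((64, 64))
        assert similarity(a, a, "MI") < similarity(a, b, "MI")

    def test_mi_matches_histogram_oracle(self, rng):
        a = rng.random((32, 32))
        b = a + 0.1 * rng.random((32, 32))
        hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=32)
        p = hist / hist.sum()
        mi = 0.0
        for i in range(32):
            for j in range(32):
                if p[i, j] > 0:
                    mi += p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
        assert similarity(a, b, "MI") == pytest.approx(-mi, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            similarity(rng.random((4, 4)), rng.random((5, 5)), "SSD")


class TestWarp:
    def test_identity_field(self, rng):
        img = ImageGrid(rng.random((16, 16)))
        out = warp(img, DeformationField.zero((16, 16)))
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_integer_shift_exact(self, rng):
        img = ImageGrid(rng.random((12, 12)))
        out = warp(img, constant_field((12, 12), 0.0, 2.0))
        np.testing.assert_allclose(out.pixels[:, :-2], img.pixels[:, 2:],
                                   atol=1e-12)

    def test_label_warp_never_invents_labels(self, small_case):
        out = warp(small_case.anatomy_ct, small_case.true_field, "nearest")
        assert set(np.unique(out.labels)) <= set(np.unique(small_case.anatomy_ct.labels))

    def test_warp_then_inverse_recovers_smooth_image(self, small_case):
        """Fixed-point inversion of the true field undoes the warp to within
        2% of the intensity range on a smooth image."""
        from scipy import ndimage
        f = DeformationField(small_case.true_field.displacement)  # unit spacing
        img = ImageGrid(ndimage.gaussian_filter(small_case.image_ct.pixels, 3.0))
        # fixed-point iteration for the inverse displacement
        H, W = f.shape
        rr, cc = np.meshgrid(np.arange(H, dtype=float),
                             np.arange(W, dtype=float), indexing="ij")
        inv = np.zeros_like(f.displacement)
        for _ in range(30):
            pr = rr + inv[:, :, 0]
            pc = cc + inv[:, :, 1]
            s = np.stack([ndimage.map_coordinates(f.displacement[:, :, i],
                                                  [pr, pc], order=1,
                                                  mode="nearest")
                          for i in range(2)], axis=-1)
            inv = -s
        inv_f = DeformationField(inv, f.spacing)
        round_trip = warp(warp(img, f), inv_f)
        inner = (slice(8, -8), slice(8, -8))  # edge extension is not invertible
        err = np.abs(round_trip.pixels - img.pixels)[inner].mean()
        assert err < 0.02 * np.ptp(img.pixels)

    def test_grid_mismatch_rejected(self, rng):
        img = ImageGrid(rng.random((8, 8)))
        with pytest.raises(ValueError):
            warp(img, DeformationField.zero((9, 9)))


class TestFieldAlgebra:
    def test_average_self_is_identity(self, rng):
        f = DeformationField(rng.standard_normal((6, 6, 2)))
        np.testing.assert_array_equal(average_fields(f, f).displacement,
                                      f.displacement)

    def test_average_with_negation_is_zero(self, rng):
        d = rng.standard_normal((6, 6, 2))
        f1 = DeformationField(d)
        f2 = DeformationField(-d)
        assert np.all(average_fields(f1, f2).displacement == 0.0)

    def test_average_matches_brute_force(self, rng):
        d1 = rng.standard_normal((5, 7, 2))
        d2 = rng.standard_normal((5, 7, 2))
        out = average_fields(DeformationField(d1), DeformationField(d2))
        for r in range(5):
            for c in range(7):
                for k in range(2):
                    assert out.displacement[r, c, k] == pytest.approx(
                        (d1[r, c, k] + d2[r, c, k]) / 2.0)

    def test_identity_affine_composes_to_same_field(self, rng):
        f = DeformationField(rng.standard_normal((8, 8, 2)))
        out = compose_affine_field(AffineTransform.identity(), f)
        np.testing.assert_allclose(out.displacement, f.displacement, atol=1e-12)

    def test_affine_with_zero_field_equals_field_form(self, rng):
        a = AffineTransform.from_params(1.5, -0.5, 0.1, 1.05, 0.95, 0.02,
                                        center=(5.0, 5.0))
        like = ImageGrid(np.zeros((12, 12)))
        composed = compose_affine_field(a, DeformationField.zero((12, 12)))
        direct = field_from_affine(a, like)
        np.testing.assert_allclose(composed.displacement, direct.displacement,
                                   atol=1e-12)

    def test_composition_matches_two_step_warp(self, small_case):
        from scipy import ndimage
        img = ImageGrid(ndimage.gaussian_filter(small_case.image_ct.pixels, 2.0))
        a = AffineTransform.from_params(1.0, -2.0, 0.05, center=(48.0, 48.0))
        f = DeformationField(0.5 * small_case.true_field.displacement,
                             spacing=(1.0, 1.0))
        img1 = ImageGrid(img.pixels, (1.0, 1.0))
        two_step = warp(warp(img1, field_from_affine(a, img1)), f)
        one_step = warp(img1, compose_affine_field(a, f))
        inner = (slice(6, -6), slice(6, -6))
        assert np.abs(two_step.pixels - one_step.pixels)[inner].mean() < 1e-2
        # at pixel centers the composed map agrees with alpha(p+u(p)) exactly
        assert np.abs(two_step.pixels - one_step.pixels)[inner].max() < 0.2


class TestAffineRegister:
    def test_identity_for_identical_images(self, small_case):
        img = small_case.image_ct
        a = affine_register(img, img, RegistrationConfig(pyramid_levels=2))
        assert np.abs(np.asarray(a.translation)).max() < 0.5 * img.spacing[0]
        np.testing.assert_allclose(a.linear, np.eye(2), atol=0.01)

    def test_translation_recovery(self, small_case):
        img = small_case.image_ct
        moving = warp(img, constant_field(img.shape, 5.0, 3.0, img.spacing))
        a = affine_register(img, moving)
        rec_px = np.asarray(a.translation) / np.asarray(img.spacing)
        np.testing.assert_allclose(rec_px, [-5.0, -3.0], atol=0.5)

    def test_rotation_recovery(self, small_case):
        img = small_case.image_ct
        ang = np.deg2rad(10.0)
        center = (np.asarray(img.shape) - 1) / 2 * np.asarray(img.spacing)
        rot = AffineTransform.from_params(0, 0, ang, center=center)
        moving = warp(img, field_from_affine(rot, img))
        a = affine_register(img, moving)
        rec = np.degrees(np.arctan2(a.linear[1, 0], a.linear[0, 0]))
        assert abs(abs(rec) - 10.0) < 1.0


class TestDemons:
    def test_identical_images_give_near_zero_field(self, small_case):
        img = small_case.image_ct
        f = demons_register(img, img)
        assert f.magnitude().max() < 0.1

    def test_recovers_planted_smooth_field(self, small_case):
        from cyclereg import endpoint_error
        img = small_case.image_ct
        truth = small_case.true_field
        fixed = warp(img, truth)
        est = demons_register(fixed, img)
        mask = small_case.anatomy_ct.labels > 0
        assert endpoint_error(est, truth, mask) < 2.0

    def test_monotone_acceptance_contract(self, small_case):
        fixed = small_case.image_tee
        moving = small_case.image_ct
        est = demons_register(fixed, moving)
        after = similarity(fixed.pixels, warp(moving, est).pixels, "SSD")
        before = similarity(fixed.pixels, moving.pixels, "SSD")
        assert after <= before + 1e-12


class TestFFD:
    def test_identical_images_give_near_zero_field(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage
        img = ImageGrid(ndimage.gaussian_filter(rng.random((48, 48)), 3.0))
        cfg = RegistrationConfig(ffd_grid_spacing=16.0, pyramid_levels=1)
        f = ffd_register(img, img, cfg)
        assert f.magnitude().max() < 0.1

    def test_recovers_single_bump(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage
        base = ndimage.gaussian_filter(rng.random((48, 48)), 2.0)
        img = ImageGrid(base)
        # a smooth bump displacement well inside one control cell
        rr, cc = np.meshgrid(np.arange(48.), np.arange(48.), indexing="ij")
        bump = 3.0 * np.exp(-(((rr - 24) / 10) ** 2 + ((cc - 24) / 10) ** 2))
        truth = DeformationField(np.stack([bump, 0.3 * bump], axis=-1))
        fixed = warp(img, truth)
        cfg = RegistrationConfig(ffd_grid_spacing=16.0, metric="SSD",
                                 powell_maxfev=400)
        est = ffd_register(fixed, img, cfg)
        mask = bump > 0.5
        err = np.sqrt(((est.displacement - truth.displacement) ** 2
                       ).sum(-1))[mask].mean()
        assert err < 2.0

    def test_dense_field_matches_bspline_oracle(self):
        from scipy import ndimage
        from cyclereg.registration import _ffd_dense
        rng = np.random.default_rng(9)
        coeffs = rng.standard_normal((6, 6, 2))
        dense = _ffd_dense(coeffs, (33, 33), 8.0)
        # oracle: scipy's spline_filter-free evaluation at scattered points
        for r, c in [(0, 0), (5, 12), (16, 16), (30, 7)]:
            for k in range(2):
                val = ndimage.map_coordinates(coeffs[:, :, k],
                                              [[r / 8.0 + 1], [c / 8.0 + 1]],
                                              order=3, prefilter=False,
                                              mode="nearest")[0]
                assert dense[r, c, k] == pytest.approx(val, abs=1e-12)
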
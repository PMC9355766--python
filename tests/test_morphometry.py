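"""Morphometry: Hough orientation, valley-spacing width, structural dispersion."""

import numpy as np
import pytest

from dentinemp import (MPImage, NoDominantOrientationError, TubuleFieldParams,
                       classify_organization, estimate_orientation_hough,
                       generate_patchwork_field, generate_tubule_field,
                       peritubule_width, structure_tensor_sd)
from dentinemp.axial import axial_distance_deg

from conftest import make_image


def stripe_image(period=5.0, orientation=0.0, jitter=0.0, n_px=256,
                 field_um=90.0, seed=0):
    p = TubuleFieldParams(period_um=period, orientation_deg=orientation,
                          jitter_deg=jitter, n_px=n_px, field_um=field_um)
    return MPImage(generate_tubule_field(p, seed=seed), "SHG",
                   p.pixel_size_um), p


class TestHough:
    @pytest.mark.parametrize("orientation", [0.0, 30.0])
    def test_recovers_stripe_orientation(self, orientation):
        img, _ = stripe_image(orientation=orientation)
        est = estimate_orientation_hough(img)
        assert axial_distance_deg(est, orientation) <= 1.0

    def test_intensity_scale_invariant(self):
        img, p = stripe_image(orientation=60.0)
        scaled = MPImage(123.0 * img.data, "SHG", p.pixel_size_um)
        assert estimate_orientation_hough(scaled) == pytest.approx(
            estimate_orientation_hough(img), abs=1e-9)

    def test_uniform_image_raises_distinct_error(self):
        flat = make_image(np.full((64, 64), 3.0))
        with pytest.raises(NoDominantOrientationError):
            estimate_orientation_hough(flat)
        # isotropic noise: no dominant orientation either
        rng = np.random.default_rng(0)
        noise = make_image(rng.uniform(0, 1, (128, 128)))
        with pytest.raises(NoDominantOrientationError):
            estimate_orientation_hough(noise)

    def test_agrees_with_structure_tensor(self):
        for ori in (20.0, 115.0):
            img, _ = stripe_image(orientation=ori, jitter=2.0, seed=3)
            h = estimate_orientation_hough(img)
            t = structure_tensor_sd(img).preferred_orientation_deg
            assert axial_distance_deg(h, t) <= 3.0


class TestWidth:
    def test_noiseless_period_recovered(self):
        img, p = stripe_image(period=5.0)
        tm = peritubule_width(img, 0.0)
        assert abs(tm.width_um - 5.0) <= p.pixel_size_um
        assert tm.n_valleys >= 2 * tm.sections_used

    def test_rotation_invariance_37deg(self):
        img0, p = stripe_image(period=5.0)
        img37, _ = stripe_image(period=5.0, orientation=37.0)
        w0 = peritubule_width(img0, 0.0).width_um
        w37 = peritubule_width(img37, 37.0).width_um
        assert abs(w0 - w37) <= p.pixel_size_um

    @pytest.mark.parametrize("period", [3.0, 4.0, 5.0, 6.0, 7.0])
    @pytest.mark.parametrize("orientation", [0.0, 30.0, 60.0, 90.0, 137.0])
    def test_unbiased_across_periods_and_orientations(self, period, orientation):
        img, p = stripe_image(period=period, orientation=orientation, seed=5)
        tm = peritubule_width(img, orientation)
        assert abs(tm.width_um - period) <= p.pixel_size_um

    def test_cohort_width_at_age_82(self):
        # width line at age 82 → 5.93 µm stripes, recovered via Hough + valleys
        img, p = stripe_image(period=5.93, orientation=20.0, jitter=2.0,
                              n_px=512, field_um=180.0, seed=8)
        ori = estimate_orientation_hough(img)
        tm = peritubule_width(img, ori)
        assert abs(tm.width_um - 5.93) <= p.pixel_size_um

    def test_valleyless_image_errors(self):
        flat = make_image(np.outer(np.linspace(0, 1, 64), np.ones(64)))
        with pytest.raises(ValueError, match="valley"):
            peritubule_width(flat, 0.0)


class TestStructuralDispersion:
    def test_aligned_field_is_organized(self):
        img, _ = stripe_image()
        om = structure_tensor_sd(img)
        assert om.sd_deg < 5.0
        assert om.org_class == "organized"

    def test_jitter_sets_dispersion(self):
        # SD should track the generator's 10° orientation jitter
        img, _ = stripe_image(orientation=30.0, jitter=10.0, n_px=512,
                              field_um=180.0, seed=2)
        om = structure_tensor_sd(img)
        assert om.sd_deg == pytest.approx(10.0, abs=2.0)

    def test_random_patchwork_is_disorganized(self):
        p = TubuleFieldParams(period_um=5.0, n_px=512, field_um=180.0)
        vals = [structure_tensor_sd(
            MPImage(generate_patchwork_field(p, seed=s), "SHG",
                    p.pixel_size_um)).sd_deg for s in (1, 2, 3)]
        assert min(vals) > 40.0

    def test_rotation_moves_mean_not_sd(self):
        a, _ = stripe_image(orientation=20.0, jitter=6.0, seed=4, n_px=384,
                            field_um=135.0)
        b, _ = stripe_image(orientation=80.0, jitter=6.0, seed=4, n_px=384,
                            field_um=135.0)
        oa, ob = structure_tensor_sd(a), structure_tensor_sd(b)
        assert abs(oa.sd_deg - ob.sd_deg) <= 1.0
        shift = axial_distance_deg(ob.preferred_orientation_deg,
                                   oa.preferred_orientation_deg)
        assert shift == pytest.approx(60.0, abs=2.0)

    def test_constant_image_errors(self):
        with pytest.raises(NoDominantOrientationError):
            structure_tensor_sd(make_image(np.ones((32, 32))))

    @pytest.mark.parametrize("sd,expected", [
        (19.9, "organized"), (20.0, "organized"), (20.1, "partial"),
        (40.0, "partial"), (40.1, "disorganized"), (52.0, "disorganized")])
    def test_class_boundaries(self, sd, expected):
        assert classify_organization(sd) == expected
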
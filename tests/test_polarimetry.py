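"""Polarimetric ρ inversion: exact round trips, sign logic, masking."""

import numpy as np
import pytest

from dentinemp import (GeometryError, MPImage, PolarimetricRenderParams,
                       PolarimetricStack, TubuleFieldParams,
                       generate_tubule_field, render_polarimetric_stack,
                       rho_magnitude, rho_map, rho_sign)


def const_stack(i0, i90, i60, px=0.35):
    mk = lambda v, a: MPImage(np.full((8, 8), float(v)), "SHG", px,
                              polarization_deg=a)
    return PolarimetricStack([mk(i0, 0.0), mk(i90, 90.0), mk(i60, 60.0)])


def rendered_stack(rho, theta=0.0, pattern=None, **pkw):
    if pattern is None:
        pattern = np.full((16, 16), 0.8)
    return render_polarimetric_stack(
        pattern, PolarimetricRenderParams(rho=rho, **pkw), theta, seed=0,
        pixel_size_um=0.35)


class TestMagnitude:
    def test_sqrt_of_parallel_perpendicular_ratio(self):
        st = const_stack(4.0, 1.0, 2.0)
        np.testing.assert_allclose(rho_magnitude(st, 0.0), 2.0)

    def test_equal_intensities_give_unity(self):
        st = const_stack(3.0, 3.0, 3.0)
        np.testing.assert_allclose(rho_magnitude(st, 0.0), 1.0)

    def test_noiseless_roundtrip_minus_269(self):
        st = rendered_stack(-2.69)
        mag = rho_magnitude(st, 0.0)
        np.testing.assert_allclose(mag[np.isfinite(mag)], 2.69, atol=1e-9)

    def test_unresolvable_geometry(self):
        mk = lambda v, a: MPImage(np.full((4, 4), v), "SHG", 0.35,
                                  polarization_deg=a)
        st = PolarimetricStack([mk(1.0, 0.0), mk(1.0, 90.0), mk(1.0, 10.0)])
        # fiber at 50°: states 0° and 10° both sit ~±50° from the axis while
        # 90° is 40° away -> par/perp roles land on states only 10° apart
        with pytest.raises(GeometryError):
            rho_magnitude(st, 50.0)


class TestSign:
    #: model intensity ratios I(60°)/I(90°) for ρ = ∓1.25: 0.9414 vs 1.8789
    @pytest.mark.parametrize("rho,expected_sign", [(-1.25, -1), (1.25, 1)])
    def test_sign_from_third_state(self, rho, expected_sign):
        st = rendered_stack(rho)
        mag = rho_magnitude(st, 0.0)
        sg = rho_sign(st, mag, 0.0)
        assert np.all(sg[np.isfinite(mag)] == expected_sign)

    def test_zero_rho_pixels_masked(self):
        st = const_stack(4.0, 1.0, 1.2)
        sg = rho_sign(st, np.zeros((8, 8)), 0.0)
        assert np.all(sg == 0)

    def test_degenerate_third_state_errors(self):
        mk = lambda v, a: MPImage(np.full((4, 4), v), "SHG", 0.35,
                                  polarization_deg=a)
        st = PolarimetricStack([mk(4.0, 0.0), mk(1.0, 90.0), mk(1.0, 2.0)])
        with pytest.raises(GeometryError, match="sign|mirror"):
            rho_sign(st, np.full((4, 4), 2.0), 0.0)


class TestRhoMap:
    @pytest.mark.parametrize("theta", [0.0, 10.0, 60.0, 90.0, 150.0])
    @pytest.mark.parametrize("rho", [-3.0, -2.0, -1.25, -0.5, 0.5, 2.0])
    def test_exact_roundtrip(self, rho, theta):
        st = rendered_stack(rho, theta=theta)
        rm = rho_map(st, theta_deg=theta)
        assert abs(rm.summary_mean - rho) / abs(rho) <= 1e-6
        vals = rm.values[rm.mask]
        assert np.max(np.abs(vals - rho)) / abs(rho) <= 1e-6

    def test_mirror_degenerate_orientations_rejected(self):
        # fibers at 30° make the 0° and 60° states indistinguishable
        for theta in (30.0, 45.0, 120.0):
            st = rendered_stack(-1.25, theta=theta)
            with pytest.raises(GeometryError, match="mirror"):
                rho_map(st, theta_deg=theta)

    def test_sign_stable_under_global_rescale(self):
        st = rendered_stack(-1.25)
        scaled = PolarimetricStack([
            MPImage(7.3 * im.data, "SHG", im.pixel_size_um,
                    polarization_deg=im.polarization_deg)
            for im in st.images])
        a = rho_map(st, theta_deg=0.0)
        b = rho_map(scaled, theta_deg=0.0)
        np.testing.assert_allclose(np.sign(a.values[a.mask]),
                                   np.sign(b.values[b.mask]))
        assert b.summary_mean == pytest.approx(a.summary_mean, abs=1e-9)

    def test_mask_monotone_in_floor(self):
        params = TubuleFieldParams(period_um=5.0, n_px=64, field_um=22.5)
        pattern = generate_tubule_field(params, seed=1)
        st = rendered_stack(-1.25, pattern=pattern, scale=100.0)
        lo = rho_map(st, theta_deg=0.0, floor=5.0)
        hi = rho_map(st, theta_deg=0.0, floor=20.0)
        # raising the floor never unmasks a pixel
        assert not np.any(hi.mask & ~lo.mask)
        assert hi.mask.sum() < lo.mask.sum()

    def test_identical_frames_give_unit_magnitude(self):
        st = const_stack(5.0, 5.0, 5.0)
        rm = rho_map(st, theta_deg=0.0)
        np.testing.assert_allclose(np.abs(rm.values[rm.mask]), 1.0)

    def test_mean_intensity_variant_matches_on_uniform(self):
        st = rendered_stack(-1.7)
        a = rho_map(st, theta_deg=0.0)
        b = rho_map(st, theta_deg=0.0, method="mean")
        assert b.summary_mean == pytest.approx(a.summary_mean, abs=1e-9)

    def test_noisy_monte_carlo_near_truth(self):
        params = TubuleFieldParams(period_um=5.0, n_px=96, field_um=33.75)
        pattern = generate_tubule_field(params, seed=0)
        means = []
        for s in range(10):
            st = render_polarimetric_stack(
                pattern, PolarimetricRenderParams(
                    rho=-1.25, scale=300.0, baseline=0.3, photon_gain=100.0),
                0.0, seed=s, pixel_size_um=params.pixel_size_um)
            means.append(rho_map(st, theta_deg=0.0).summary_mean)
        assert np.mean(means) == pytest.approx(-1.25, abs=0.05)
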
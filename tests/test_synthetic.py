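"""Synthetic generator: geometry, intensity statistics, determinism."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from dentinemp import (ChannelRenderParams, CohortConfig,
                       PolarimetricRenderParams, TubuleFieldParams,
                       cohort_truth, generate_cohort, generate_tubule_field,
                       inag_to_ratio, render_channel_pair,
                       render_polarimetric_stack, shg_response,
                       simulate_to_dir, MPImage)

from conftest import make_pair


def autocorr_period_um(field: np.ndarray, pixel_size_um: float) -> float:
    """Independent period oracle: first autocorrelation peak of the mean
    profile along the stripe normal (rows, for a 0° field)."""
    prof = field.mean(axis=1)
    prof = prof - prof.mean()
    ac = np.correlate(prof, prof, "full")[len(prof) - 1:]
    peaks, _ = find_peaks(ac)
    return float(peaks[0]) * pixel_size_um


class TestTubuleField:
    def test_period_matches_autocorrelation(self):
        params = TubuleFieldParams(period_um=5.0, n_px=512, field_um=180.0)
        field = generate_tubule_field(params, seed=1)
        assert field.min() >= 0.0 and field.max() <= 1.0
        period = autocorr_period_um(field, params.pixel_size_um)
        assert abs(period - 5.0) <= params.pixel_size_um

    def test_orientation_90_is_transpose(self):
        p0 = TubuleFieldParams(period_um=5.0, n_px=256, field_um=90.0)
        p90 = TubuleFieldParams(period_um=5.0, orientation_deg=90.0,
                                n_px=256, field_um=90.0)
        f0 = generate_tubule_field(p0, seed=3)
        f90 = generate_tubule_field(p90, seed=3)
        np.testing.assert_allclose(f90, f0.T, atol=1e-12)

    def test_width_line_at_age_19(self):
        # width line evaluated at age 19: 0.03*19 + 3.47 = 4.04 µm
        params = TubuleFieldParams(period_um=4.04, n_px=512, field_um=180.0)
        field = generate_tubule_field(params, seed=2)
        # valley (minima) spacing of the mean profile, independent oracle
        prof = field.mean(axis=1)
        valleys, _ = find_peaks(-prof, prominence=0.1 * np.ptp(prof))
        spacing = np.median(np.diff(valleys)) * params.pixel_size_um
        assert abs(spacing - 4.04) <= params.pixel_size_um

    def test_nyquist_rejected(self):
        params = TubuleFieldParams(period_um=0.5, n_px=256, field_um=90.0)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_tubule_field(params, seed=0)

    @pytest.mark.parametrize("bad", [
        dict(duty=0.0), dict(duty=1.0), dict(jitter_deg=-1.0),
        dict(ridge_contrast=1.5)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_tubule_field(
                TubuleFieldParams(period_um=5.0, n_px=128, field_um=45.0, **bad),
                seed=0)


class TestChannelPair:
    def test_ratio_one_noiseless_identical(self):
        tpef, shg = make_pair(1.0)
        np.testing.assert_array_equal(tpef.data, shg.data)

    def test_ratio_exact_noiseless(self):
        tpef, shg = make_pair(0.57)
        assert shg.data.mean() / tpef.data.mean() == pytest.approx(0.57,
                                                                   abs=1e-12)

    def test_poisson_ratio_mean_and_shrinking_sd(self):
        # measured ratios concentrate on 0.39; spread shrinks with gain
        sds = {}
        for gain in (0.5, 8.0):
            ratios = [make_pair(0.39, seed=s, noiseless=False,
                                photon_gain=gain)[1].data.mean()
                      / make_pair(0.39, seed=s, noiseless=False,
                                  photon_gain=gain)[0].data.mean()
                      for s in range(10)]
            assert np.mean(ratios) == pytest.approx(0.39, abs=0.01)
            sds[gain] = np.std(ratios)
        assert sds[8.0] < sds[0.5]

    def test_invalid_ratio_rejected(self):
        for ratio in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                make_pair(ratio)


class TestPolarimetricRender:
    #: forward-model point values at θ=0, ρ=−1.25: ρ² at Δ=0; 1 at Δ=90°;
    #: 0.75 + (0.75 − 0.3125)² at Δ=60°
    CASES = [(0.0, 1.5625), (90.0, 1.0), (60.0, 0.94140625)]

    @pytest.mark.parametrize("alpha,expected", CASES)
    def test_point_intensities(self, alpha, expected):
        pattern = np.ones((4, 4))
        stack = render_polarimetric_stack(
            pattern, PolarimetricRenderParams(rho=-1.25), 0.0, seed=0,
            pixel_size_um=0.35)
        idx = list(stack.angles_deg).index(alpha)
        np.testing.assert_allclose(stack.images[idx].data, expected)

    def test_half_turn_periodicity(self):
        for rho in (-1.25, 0.7):
            assert shg_response(37.0, rho) == pytest.approx(
                shg_response(37.0 + 180.0, rho), abs=1e-12)

    def test_fiber_rotation_swaps_par_perp(self):
        # rotating the fiber by 90° exchanges the 0° and 90° frames
        pattern = np.full((4, 4), 0.6)
        a = render_polarimetric_stack(pattern,
                                      PolarimetricRenderParams(rho=-2.0),
                                      0.0, seed=0, pixel_size_um=0.35)
        b = render_polarimetric_stack(pattern,
                                      PolarimetricRenderParams(rho=-2.0),
                                      90.0, seed=0, pixel_size_um=0.35)
        np.testing.assert_allclose(a.images[0].data, b.images[1].data)
        np.testing.assert_allclose(a.images[1].data, b.images[0].data)

    def test_requires_orthogonal_pair(self):
        with pytest.raises(ValueError, match="orthogonal"):
            render_polarimetric_stack(
                np.ones((4, 4)),
                PolarimetricRenderParams(rho=-1.0, angles_deg=(0.0, 45.0, 60.0)),
                0.0, seed=0, pixel_size_um=0.35)


ZERO_RESID = {"width": 0.0, "inag": 0.0, "rho": 0.0}


class TestCohort:
    def test_truth_at_age_24(self):
        cfg = CohortConfig(ages_years=(24.0, 50.0, 80.0),
                           residual_sds=ZERO_RESID)
        truth = cohort_truth(cfg)
        row = truth.iloc[0]
        assert row["inag_true"] == pytest.approx(-0.322, abs=1e-12)
        assert row["ratio_true"] == pytest.approx(0.678 / 1.322, abs=1e-12)

    def test_truth_at_age_82(self):
        cfg = CohortConfig(ages_years=(82.0, 20.0, 50.0),
                           residual_sds=ZERO_RESID)
        assert cohort_truth(cfg).iloc[0]["width_true_um"] == pytest.approx(
            5.93, abs=1e-12)

    def test_zero_residual_truth_collinear(self):
        cfg = CohortConfig(residual_sds=ZERO_RESID)
        truth = cohort_truth(cfg)
        r = np.corrcoef(truth["age_years"], truth["width_true_um"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_inag_rejected(self):
        assert inag_to_ratio(-0.322) == pytest.approx(0.5129, abs=5e-5)
        with pytest.raises(ValueError, match="ratio undefined|outside"):
            inag_to_ratio(-1.0)
        cfg = CohortConfig(ages_years=(40.0,), inag_line=(0.0, -1.2),
                           residual_sds=ZERO_RESID)
        with pytest.raises(ValueError):
            cohort_truth(cfg)

    def test_seed_determinism_bit_identical(self):
        cfg = CohortConfig(ages_years=(25.0, 60.0), regions_per_specimen=1,
                           n_px=64, field_um=22.5, seed=7)
        (a, ta), (b, tb) = generate_cohort(cfg), generate_cohort(cfg)
        assert ta.equals(tb)
        for sa, sb in zip(a, b):
            for ra, rb in zip(sa.regions, sb.regions):
                np.testing.assert_array_equal(ra.shg.data, rb.shg.data)
                np.testing.assert_array_equal(ra.tpef.data, rb.tpef.data)
        c, _ = generate_cohort(CohortConfig(ages_years=(25.0, 60.0),
                                            regions_per_specimen=1, n_px=64,
                                            field_um=22.5, seed=8))
        assert not np.array_equal(a[0].regions[0].shg.data,
                                  c[0].regions[0].shg.data)

    def test_simulate_to_dir_roundtrip(self, tmp_path):
        cfg = CohortConfig(ages_years=(30.0,), regions_per_specimen=1,
                           n_px=64, field_um=22.5, seed=1)
        truth = simulate_to_dir(cfg, tmp_path)
        assert (tmp_path / "ground_truth.csv").exists()
        tif = tmp_path / "S01" / "region_00_shg.tif"
        img = MPImage.load(tif)
        assert img.channel == "SHG"
        assert img.meta["age_years"] == 30.0
        assert img.pixel_size_um == pytest.approx(22.5 / 64)
        pol = sorted((tmp_path / "S01").glob("region_00_shg_pol*.tif"))
        assert len(pol) == 3
        assert truth.iloc[0]["specimen_id"] == "S01"
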
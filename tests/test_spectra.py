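"""Spectral stage: window geometry, phantom normalization and the seven
parameter estimators, each checked against analytic oracles and against the
simulator's ground truth."""

import numpy as np
import pytest

from qusrecur import simulate, spectra
from qusrecur.simulate import GAUSS_FF_CONST

from conftest import toy_acquisition


class TestWindowGrid:
    def test_axial_window_is_104_samples_at_40mhz(self, acq):
        # c/(2 fs) = 19.25 um -> 2 mm / 19.25 um = 103.9 -> 104 samples
        mask = np.ones((acq.n_axial_samples, acq.n_lines), dtype=bool)
        g = spectra.build_window_grid(mask.shape, mask, acq)
        assert g.window_axial == 104
        assert g.step_axial == max(1, round(0.08 * 104))

    def test_enumeration_on_toy_grid(self):
        # 10 px window, 92 % overlap -> step max(1, round(0.8)) = 1;
        # a 20x20 fully-masked slice admits 11x11 = 121 windows
        tacq = toy_acquisition(window_px=10)
        mask = np.ones((20, 20), dtype=bool)
        g = spectra.build_window_grid((20, 20), mask, tacq)
        assert g.window_axial == 10 and g.window_lateral == 10
        assert g.step_axial == 1 and g.step_lateral == 1
        assert g.n_windows == 121

    def test_empty_mask_raises(self, acq):
        mask = np.zeros((acq.n_axial_samples, acq.n_lines), dtype=bool)
        with pytest.raises(ValueError, match="empty ROI"):
            spectra.build_window_grid(mask.shape, mask, acq)

    def test_roi_smaller_than_window_raises(self):
        tacq = toy_acquisition(window_px=10)
        with pytest.raises(ValueError, match="smaller than analysis window"):
            spectra.build_window_grid((8, 8), np.ones((8, 8), bool), tacq)

    def test_centers_inside_mask_only(self, acq):
        mask = np.zeros((acq.n_axial_samples, acq.n_lines), dtype=bool)
        mask[300:900, 40:120] = True
        g = spectra.build_window_grid(mask.shape, mask, acq)
        ctr = g.centers()
        assert np.all(mask[ctr[:, 0], ctr[:, 1]])


class TestNormalizedSpectrum:
    def test_identity_input_gives_zero_db(self, acq):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, (104, 13))
        f, s = spectra.normalized_spectrum(w, w, acq)
        np.testing.assert_allclose(s, 0.0, atol=1e-9)
        assert f[0] >= acq.band_low and f[-1] <= acq.band_high

    def test_double_amplitude_gives_6db(self, acq):
        rng = np.random.default_rng(1)
        w = rng.normal(0, 1, (104, 13))
        _, s = spectra.normalized_spectrum(2.0 * w, w, acq)
        np.testing.assert_allclose(s, 20 * np.log10(2.0), atol=1e-9)

    def test_zero_phantom_raises(self, acq):
        w = np.random.default_rng(2).normal(0, 1, (104, 13))
        with pytest.raises(ValueError, match="phantom power"):
            spectra.normalized_spectrum(w, np.zeros_like(w), acq)

    def test_shape_mismatch_raises(self, acq):
        w = np.zeros((104, 13))
        with pytest.raises(ValueError, match="match"):
            spectra.normalized_spectrum(w, w[:, :4], acq)


class TestLineFit:
    def test_exact_line(self):
        f = np.linspace(3e6, 8e6, 65)
        s = 2.0 * (f / 1e6) + 3.0
        mbf, ss, si = spectra.fit_mbf_ss_si(s, f, 5.5e6)
        assert ss == pytest.approx(2.0, abs=1e-12)
        assert si == pytest.approx(3.0, abs=1e-10)
        assert mbf == pytest.approx(14.0, abs=1e-10)

    def test_flat_spectrum(self):
        f = np.linspace(3e6, 8e6, 65)
        mbf, ss, si = spectra.fit_mbf_ss_si(np.full(65, 5.0), f, 6.5e6)
        assert (mbf, ss, si) == pytest.approx((5.0, 0.0, 5.0), abs=1e-12)

    def test_noisy_line_recovery(self):
        # OLS sampling error over 101 points with 0.1 dB noise keeps the
        # slope within +/- 0.05 dB/MHz
        rng = np.random.default_rng(7)
        f = np.linspace(3e6, 8e6, 101)
        s = 2.0 * (f / 1e6) + 3.0 + rng.normal(0, 0.1, 101)
        _, ss, _ = spectra.fit_mbf_ss_si(s, f, 6.5e6)
        assert ss == pytest.approx(2.0, abs=0.05)

    def test_identity_holds_for_random_spectra(self):
        rng = np.random.default_rng(3)
        f = np.linspace(3e6, 8e6, 65)
        s = rng.normal(0, 5, (40, 65))
        mbf, ss, si = spectra.fit_mbf_ss_si(s, f, 6.5e6)
        np.testing.assert_allclose(mbf, ss * 6.5 + si, atol=1e-9)

    def test_nonfinite_raises(self):
        f = np.linspace(3e6, 8e6, 65)
        s = np.full(65, np.nan)
        with pytest.raises(ValueError):
            spectra.fit_mbf_ss_si(s, f, 6.5e6)


class TestAsdAac:
    def test_forward_model_inversion(self, acq):
        # spectrum built from the Gaussian form factor with a = 25 um
        a = 25e-6
        f = np.linspace(3e6, 8e6, 65)
        k2 = (2 * np.pi * f / acq.sound_speed) ** 2
        s_db = 10 * np.log10(np.exp(-GAUSS_FF_CONST * k2 * a * a))
        asd, _, flag = spectra.estimate_asd_aac(s_db, f, acq)
        assert asd == pytest.approx(50.0, rel=0.10)
        assert not flag

    def test_zero_radius_clips_to_lower_bound(self, acq):
        f = np.linspace(3e6, 8e6, 65)
        asd, _, flag = spectra.estimate_asd_aac(np.zeros(65), f, acq)
        assert asd == spectra.ASD_RANGE_UM[0]
        assert flag

    def test_concentration_doubling_shifts_aac_3db(self, acq):
        f = np.linspace(3e6, 8e6, 65)
        s1 = np.full(65, -2.0)
        s2 = s1 + 10 * np.log10(2.0)
        _, aac1, _ = spectra.estimate_asd_aac(s1, f, acq)
        _, aac2, _ = spectra.estimate_asd_aac(s2, f, acq)
        assert aac2 - aac1 == pytest.approx(10 * np.log10(2.0), abs=0.5)


class TestSas:
    def test_cosine_ripple(self, acq):
        # ripple period 0.77 MHz <-> spacing c/(2 * 0.77e6) = 1.00 mm
        f = np.linspace(3e6, 8e6, 129)
        p = 1.0 + 0.5 * np.cos(2 * np.pi * f / 0.77e6)
        sas, flag = spectra.estimate_sas(p, f, acq)
        assert not flag
        assert sas == pytest.approx(1.0, rel=0.05)

    def test_flat_spectrum_flagged_fallback(self, acq):
        f = np.linspace(3e6, 8e6, 129)
        sas, flag = spectra.estimate_sas(np.ones(129), f, acq)
        assert flag
        assert sas == spectra.SAS_RANGE_MM[1]

    def test_narrow_band_raises(self, acq):
        f = np.linspace(3e6, 3.2e6, 16)
        with pytest.raises(ValueError, match="narrower"):
            spectra.estimate_sas(np.ones(16), f, acq)

    def test_simulated_spacing_median_window(self, acq, phantom_ref):
        t = simulate.TissueSpec(effective_scatterer_radius=25e-6,
                                mean_regular_spacing=1.5e-3,
                                spacing_jitter=0.1, attenuation_coeff=0.5)
        e = simulate.simulate_exam(acq, t, n_slices=1, seed=0)
        sf = spectra.extract_slice(e.slices[0], e.masks[0], phantom_ref, acq)
        assert 1.35 <= np.median(sf.window_values["SAS"]) <= 1.65


class TestAce:
    def test_analytic_decay_exact(self, acq):
        # S = const(f) - 2 * alpha * f * z with alpha = 0.5
        f = np.linspace(3e6, 8e6, 65)
        depth_cm = 0.5 + 0.154 * np.arange(12)
        s = 3.0 - 2 * 0.5 * (f / 1e6)[None, :] * depth_cm[:, None]
        row = np.repeat(np.arange(12), 3)
        ace = spectra.estimate_ace(s[row], row, depth_cm, f)
        assert ace == pytest.approx(0.5, abs=1e-9)

    def test_too_few_rows_raises(self, acq):
        f = np.linspace(3e6, 8e6, 65)
        s = np.zeros((4, 65))
        row = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="3 window rows"):
            spectra.estimate_ace(s, row, np.array([1.0, 1.1]), f)

    def test_zero_attenuation_near_zero(self, flat_slice):
        assert abs(flat_slice.ace) < 0.1

    def test_attenuation_linearity(self, acq, phantom_ref):
        """Doubling the simulated attenuation doubles the estimate (20 %)."""
        aces = []
        for alpha in (0.25, 0.5):
            t = simulate.TissueSpec(effective_scatterer_radius=0.0,
                                    mean_regular_spacing=0.0,
                                    attenuation_coeff=alpha)
            vals = []
            for seed in (31, 32, 33):
                e = simulate.simulate_exam(acq, t, n_slices=1, seed=seed)
                vals.append(spectra.extract_slice(
                    e.slices[0], e.masks[0], phantom_ref, acq).ace)
            aces.append(np.mean(vals))
        assert aces[1] / aces[0] == pytest.approx(2.0, rel=0.20)


class TestExtractSlice:
    def test_mbf_identity_per_window(self, structured_extraction):
        for sf in structured_extraction.slices:
            w = sf.window_values
            np.testing.assert_allclose(
                w["MBF"], w["SS"] * 6.5 + w["SI"], atol=1e-9)

    def test_clip_ranges(self, structured_extraction):
        for sf in structured_extraction.slices:
            asd = sf.window_values["ASD"]
            sas = sf.window_values["SAS"]
            assert np.all((asd >= 1.0) & (asd <= 200.0))
            assert np.all((sas >= 0.2) & (sas <= 2.5))

    def test_maps_nan_outside_roi(self, structured_extraction):
        sf = structured_extraction.slices[0]
        m = sf.maps["MBF"]
        assert np.isnan(m).any()
        assert np.isfinite(m[sf.grid.lattice_index[:, 0],
                             sf.grid.lattice_index[:, 1]]).all()

    def test_amplitude_rescale_invariance(self, acq, phantom, flat_exam):
        """Scaling tissue AND phantom RF by one factor leaves every estimate
        unchanged (the normalization is a pure ratio)."""
        ref = spectra.PhantomReference([s * 7.3 for s in phantom.slices])
        sf1 = spectra.extract_slice(flat_exam.slices[0], flat_exam.masks[0],
                                    spectra.PhantomReference(phantom.slices),
                                    acq)
        sf2 = spectra.extract_slice(flat_exam.slices[0] * 7.3,
                                    flat_exam.masks[0], ref, acq)
        for k in sf1.window_means:
            assert sf1.window_means[k] == pytest.approx(
                sf2.window_means[k], rel=1e-9, abs=1e-9)
        assert sf1.ace == pytest.approx(sf2.ace, abs=1e-9)

    def test_asd_monotone_in_radius(self, acq, phantom_ref):
        """Median window ASD strictly increases across 10/25/50 um radii."""
        medians = []
        for radius in (10e-6, 25e-6, 50e-6):
            t = simulate.TissueSpec(effective_scatterer_radius=radius,
                                    mean_regular_spacing=0.0,
                                    attenuation_coeff=0.0)
            e = simulate.simulate_exam(acq, t, n_slices=1, seed=13)
            sf = spectra.extract_slice(e.slices[0], e.masks[0],
                                       phantom_ref, acq)
            assert sf.n_windows >= 100
            medians.append(np.median(sf.window_values["ASD"]))
        assert medians[0] < medians[1] < medians[2]

    def test_flat_spectrum_slope_small(self, flat_slice):
        """Diffuse point-scatterer tissue against a phantom from the same
        pulse: the normalized spectrum is flat (|SS| < 0.3 dB/MHz averaged
        over >= 100 windows)."""
        assert flat_slice.n_windows >= 100
        assert abs(flat_slice.window_means["SS"]) < 0.3
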
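import numpy as np
import pytest
from scipy.integrate import quad

from smartdrt import (
    EarModelParams,
    RoexShape,
    SignalSpec,
    Stimulus,
    cam_from_hz,
    erb_n_hz,
    excitation_noise,
    excitation_tone,
    filter_slopes,
    hit_probability,
    hz_from_cam,
    predict_ptc,
)
from smartdrt.excitation import noise_bandwidth_hz, signal_excitation_at_edge


class TestFilterSlopes:
    def test_normal_reference_sharpness(self):
        shape = filter_slopes(1000.0, 51.0, 0.0)
        assert shape.p_upper == pytest.approx(4000.0 / erb_n_hz(1000.0))
        assert shape.p_upper == pytest.approx(30.16, abs=0.01)
        assert shape.p_lower == shape.p_upper

    def test_no_level_correction_at_or_below_reference(self):
        for cf in (500.0, 1000.0, 4000.0):
            at_ref = filter_slopes(cf, 51.0, 0.0)
            below = filter_slopes(cf, 30.0, 0.0)
            assert at_ref.p_lower == below.p_lower == at_ref.p_upper

    def test_lower_skirt_broadens_with_level_and_ohcl(self):
        base = filter_slopes(1000.0, 51.0, 0.0).p_lower
        assert filter_slopes(1000.0, 80.0, 0.0).p_lower < base
        assert filter_slopes(1000.0, 51.0, 30.0).p_lower < base

    def test_cap_reaches_floor_and_clips_with_warning(self):
        shape = filter_slopes(1000.0, 51.0, 65.0)
        assert shape.p_lower == pytest.approx(0.2 * shape.p_upper)
        with pytest.warns(UserWarning, match="cap"):
            clipped = filter_slopes(1000.0, 51.0, 80.0)
        assert clipped.p_lower == shape.p_lower

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            RoexShape(1000.0, p_lower=40.0, p_upper=30.0)


class TestExcitationTone:
    def test_on_frequency_tone_excites_at_own_level(self):
        shape = filter_slopes(1000.0, 51.0, 10.0)
        assert excitation_tone(shape, 1000.0, 63.0) == pytest.approx(63.0)

    def test_hand_computed_point(self):
        # g = 0.25, p = 20: W = (1 + 5) e^-5, E = 80 + 10 log10(W)
        shape = RoexShape(1000.0, p_lower=20.0, p_upper=20.0)
        e = excitation_tone(shape, 1250.0, 80.0)
        assert e == pytest.approx(80.0 + 10 * np.log10(6 * np.exp(-5)), abs=1e-9)
        assert e == pytest.approx(66.1, abs=0.05)

    def test_weighting_depends_on_relative_offset_magnitude(self):
        shape = RoexShape(1000.0, p_lower=25.0, p_upper=25.0)
        # same |g| on both sides gives the same excitation
        e_lo = excitation_tone(shape, 800.0, 70.0)
        e_hi = excitation_tone(shape, 1200.0, 70.0)
        assert e_lo == pytest.approx(e_hi)


class TestExcitationNoise:
    def test_bandwidth_rule(self):
        assert noise_bandwidth_hz(500.0) == 200.0  # ERB_N(0.5 kHz) ≈ 78.7 < 200
        assert erb_n_hz(500.0) == pytest.approx(78.67, abs=0.01)
        f_hi = 8000.0
        assert noise_bandwidth_hz(f_hi) == pytest.approx(erb_n_hz(f_hi))

    def test_narrow_band_converges_to_tone(self):
        shape = filter_slopes(1000.0, 60.0, 20.0)
        for f_mask in (700.0, 1000.0, 1200.0):
            x = Stimulus(f_mask, 60.0)
            e_noise = excitation_noise(shape, x, bandwidth_hz=1.0)
            e_tone = excitation_tone(shape, f_mask, 60.0)
            assert e_noise == pytest.approx(e_tone, abs=0.1)

    @pytest.mark.parametrize("f_mask, l_mask", [(800.0, 70.0), (1000.0, 55.0),
                                                (1500.0, 80.0), (120.0, 60.0)])
    def test_band_integral_matches_numerical_quadrature(self, f_mask, l_mask):
        """Independent oracle: scipy quadrature of the roex weighting."""
        shape = filter_slopes(1000.0, l_mask, 25.0)
        x = Stimulus(f_mask, l_mask)
        b = float(noise_bandwidth_hz(f_mask))
        lo = max(f_mask - b / 2, 20.0)
        hi = f_mask + b / 2

        def w(f):
            g = (f - shape.cf_hz) / shape.cf_hz
            p = shape.p_lower if f < shape.cf_hz else shape.p_upper
            return (1 + p * abs(g)) * np.exp(-p * abs(g))

        integral, _ = quad(w, lo, hi, points=[shape.cf_hz] if lo < shape.cf_hz < hi else None,
                           limit=200)
        expected = l_mask + 10 * np.log10(integral / (hi - lo))
        got = excitation_noise(shape, x)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_band_covering_filter_approaches_spectrum_level_plus_integral(self):
        shape = filter_slopes(1000.0, 70.0, 0.0)
        x = Stimulus(1000.0, 70.0)
        wide = excitation_noise(shape, x, bandwidth_hz=1900.0)
        n0 = 70.0 - 10 * np.log10(1900.0)  # spectrum level, dB/Hz
        full_integral = shape.cf_hz * (2 / shape.p_lower + 2 / shape.p_upper)
        assert wide == pytest.approx(n0 + 10 * np.log10(full_integral), abs=0.05)

    def test_background_floor_dominates_at_low_masker_level(self):
        shape = filter_slopes(1000.0, 51.0, 0.0)
        x = Stimulus(700.0, 20.0)
        with_bg = excitation_noise(shape, x, background_ten_db=35.0)
        without = excitation_noise(shape, x)
        assert with_bg >= 35.0 - 0.1
        assert with_bg > without


class TestHitProbability:
    def test_half_at_predicted_masked_threshold(self, cohort):
        p = cohort[0]
        a = p.audiogram
        sig = SignalSpec(hz_from_cam(cam_from_hz(p.true_fe_hz) + 1.0),
                         a.hl_at(p.true_fe_hz) + 15.0)
        theta = EarModelParams(p.true_fe_hz, p.true_ohcl_db)
        f_grid = np.array([hz_from_cam(cam_from_hz(p.true_fe_hz) - 0.5)])
        levels, inaudible = predict_ptc(theta, sig, a, f_grid)
        assert not inaudible and np.isfinite(levels[0])
        pr = hit_probability(Stimulus(float(f_grid[0]), float(levels[0])),
                             theta, sig, a)
        assert pr == pytest.approx(0.5, abs=1e-6)

    def test_probability_range_and_asymptotes(self, cohort):
        p = cohort[0]
        a = p.audiogram
        sig = SignalSpec(hz_from_cam(cam_from_hz(p.true_fe_hz) + 1.0),
                         a.hl_at(p.true_fe_hz) + 15.0)
        theta = EarModelParams(p.true_fe_hz, p.true_ohcl_db)
        probs = [
            hit_probability(Stimulus(f, l), theta, sig, a)
            for f in (p.true_fe_hz * 0.8, p.true_fe_hz)
            for l in (20.0, 50.0, 90.0)
        ]
        assert all(0.01 <= q <= 0.99 for q in probs)

    def test_monotone_in_masker_level_and_signal_level(self, cohort):
        p = cohort[1]
        a = p.audiogram
        theta = EarModelParams(p.true_fe_hz, p.true_ohcl_db)
        f_sig = hz_from_cam(cam_from_hz(p.true_fe_hz) + 1.0)
        base_l = a.hl_at(p.true_fe_hz) + 15.0
        f_mask = p.true_fe_hz * 0.95
        probs = [hit_probability(Stimulus(f_mask, l), theta,
                                 SignalSpec(f_sig, base_l), a)
                 for l in np.arange(20.0, 91.0, 2.0)]
        assert np.all(np.diff(probs) <= 1e-12)
        probs_sig = [hit_probability(Stimulus(f_mask, 70.0), theta,
                                     SignalSpec(f_sig, l), a)
                     for l in np.arange(base_l, base_l + 20.0, 1.0)]
        assert np.all(np.diff(probs_sig) >= -1e-12)

    def test_invalid_theta_rejected(self, cohort):
        p = cohort[0]
        a = p.audiogram
        sig = SignalSpec(p.true_fe_hz * 1.2, 80.0)
        with pytest.raises(ValueError):
            hit_probability(Stimulus(800.0, 60.0),
                            EarModelParams(sig.f_sig_hz * 1.1, 10.0), sig, a)
        with pytest.raises(ValueError):
            hit_probability(Stimulus(800.0, 60.0),
                            EarModelParams(p.true_fe_hz,
                                           a.hl_at(p.true_fe_hz) + 5.0), sig, a)


class TestPredictPtc:
    def _dr_setup(self, profile):
        a = profile.audiogram
        f_sig = hz_from_cam(cam_from_hz(profile.true_fe_hz) + 1.2)
        sig = SignalSpec(f_sig, a.hl_at(profile.true_fe_hz) + 15.0)
        return a, sig

    def test_tip_near_edge_frequency(self, standard_cohort):
        """For dead-region configurations the tuning-curve minimum falls
        within 0.25 Cams of f_e (brute-force scan over a dense grid)."""
        for profile in standard_cohort[:4]:
            if profile.true_ohcl_db < 20.0:
                continue
            a, sig = self._dr_setup(profile)
            theta = EarModelParams(profile.true_fe_hz, profile.true_ohcl_db)
            fe_cam = cam_from_hz(profile.true_fe_hz)
            grid_cam = np.arange(fe_cam - 3.0, min(fe_cam + 1.0,
                                 cam_from_hz(sig.f_sig_hz) - 0.05), 0.05)
            levels, flag = predict_ptc(theta, sig, a, hz_from_cam(grid_cam))
            assert not flag
            finite = np.isfinite(levels)
            assert finite.any()
            tip = grid_cam[finite][np.argmin(levels[finite])]
            assert abs(tip - fe_cam) <= 0.25

    def test_higher_ohcl_flattens_curve(self, standard_cohort):
        profile = standard_cohort[0]
        a, sig = self._dr_setup(profile)
        fe = profile.true_fe_hz
        hl_fe = a.hl_at(fe)
        grid = hz_from_cam(np.arange(cam_from_hz(fe) - 3.0, cam_from_hz(fe) + 0.5, 0.1))
        lo, _ = predict_ptc(EarModelParams(fe, 10.0), sig, a, grid)
        hi, _ = predict_ptc(EarModelParams(fe, min(hl_fe, 55.0)), sig, a, grid)
        both = np.isfinite(lo) & np.isfinite(hi)
        assert both.sum() >= 5
        assert np.ptp(hi[both]) < np.ptp(lo[both])

    def test_inaudible_signal_flags_everything(self, sloping_audiogram):
        a = sloping_audiogram
        # probe far above the edge: upper-skirt attenuation sinks E_sig below HL
        theta = EarModelParams(800.0, 20.0)
        sig = SignalSpec(3000.0, a.hl_at(3000.0) + 10.0)
        levels, flag = predict_ptc(theta, sig, a, np.array([700.0, 900.0]))
        assert flag
        assert np.isnan(levels).all()

    def test_edge_audibility_uses_upper_skirt_only(self, cohort):
        p = cohort[0]
        sig = SignalSpec(hz_from_cam(cam_from_hz(p.true_fe_hz) + 1.0), 80.0)
        e = float(signal_excitation_at_edge(p.true_fe_hz, sig))
        assert e < sig.l_sig_db  # attenuated, but independent of masker level
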
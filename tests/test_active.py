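import numpy as np
import pytest
from scipy.stats import chisquare

from smartdrt import (
    CandidateGrid,
    SessionConfig,
    SignalSpec,
    Stimulus,
    cam_from_hz,
    hz_from_cam,
    initial_grid,
    mutual_information,
    run_session,
    select_next_stimulus,
    stopping_check,
)
from smartdrt.active import (
    _selection_weights,
    mutual_information_vector,
    practice_stimuli,
)
from smartdrt.engine import build_prior


class TestInitialGrid:
    def test_structure(self):
        sig = SignalSpec(2000.0, 75.0)
        stims = initial_grid(sig)
        assert len(stims) == 16
        cam_sig = cam_from_hz(2000.0)
        assert stims[0].f_mask_hz == pytest.approx(hz_from_cam(cam_sig - 2.0))
        assert stims[0].l_mask_db == 75.0 - 20.0
        assert stims[8].f_mask_hz == pytest.approx(hz_from_cam(cam_sig - 4.0))
        rel = [s.l_mask_db - 75.0 for s in stims[:8]]
        assert rel == [-20, -9, -6, -3, 0, 3, 6, 9]
        assert rel == sorted(rel)

    def test_levels_clipped_with_warning(self):
        sig = SignalSpec(2000.0, 85.0)  # +9 would exceed 90 dB HL
        with pytest.warns(UserWarning, match="clipped"):
            stims = initial_grid(sig)
        assert max(s.l_mask_db for s in stims) == 90.0

    def test_practice_trials_are_easy_pairs(self):
        sig = SignalSpec(2000.0, 75.0)
        stims = practice_stimuli(sig)
        assert len(stims) == 4
        assert len({s.f_mask_hz for s in stims}) == 1
        assert sorted({s.l_mask_db for s in stims}) == [45.0, 85.0]


class TestMutualInformation:
    def test_point_mass_posterior_gives_zero(self, sloping_audiogram):
        sig = SignalSpec(2000.0, 80.0)
        prob = np.zeros(5)
        prob[2] = 1.0
        p_hit = np.linspace(0.05, 0.95, 5)[:, None]
        assert mutual_information_vector(prob, p_hit)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_cell_value(self):
        # Hb(0.5) - [Hb(0.01) + Hb(0.99)]/2 = 1 - Hb(0.01)
        prob = np.array([0.5, 0.5])
        p_hit = np.array([[0.01], [0.99]])
        hb001 = -(0.01 * np.log2(0.01) + 0.99 * np.log2(0.99))
        got = mutual_information_vector(prob, p_hit)[0]
        assert got == pytest.approx(1.0 - hb001, abs=1e-12)
        assert got == pytest.approx(0.9192, abs=5e-4)

    def test_bounded_by_one_bit_over_candidate_lattice(self, sloping_audiogram):
        sig = SignalSpec(2000.0, 80.0)
        prior = build_prior(sloping_audiogram, sig)
        cand = CandidateGrid.for_signal(sig)
        mi = [
            mutual_information(prior, Stimulus(f, l), sig, sloping_audiogram)
            for f, l in zip(cand.f_mask_hz[::17], cand.l_mask_db[::17])
        ]
        assert all(0.0 <= m <= 1.0 for m in mi)


class TestSelection:
    def test_single_positive_weight_always_selected(self, sloping_audiogram):
        sig = SignalSpec(2000.0, 80.0)
        prior = build_prior(sloping_audiogram, sig)
        cand = CandidateGrid.for_signal(sig, cam_step=2.0, level_step_db=35.0)
        rng = np.random.default_rng(0)
        # exclusion centred so that exactly candidates near one frequency survive
        fe_hat = float(cand.f_mask_cam.min())
        prev = hz_from_cam(float(cand.f_mask_cam.max()))
        chosen = {
            select_next_stimulus(prior, cand, fe_hat, prev, rng, sig,
                                 sloping_audiogram)[0].f_mask_hz
            for _ in range(50)
        }
        surviving = cand.f_mask_cam[
            np.abs(cand.f_mask_cam - cam_from_hz(prev)) >= 2.0
        ]
        assert {round(cam_from_hz(f), 6) for f in chosen} <= {
            round(c, 6) for c in surviving
        }

    def test_exclusion_zone_never_selected(self, sloping_audiogram):
        sig = SignalSpec(2000.0, 80.0)
        prior = build_prior(sloping_audiogram, sig)
        cand = CandidateGrid.for_signal(sig, cam_step=1.0, level_step_db=20.0)
        rng = np.random.default_rng(1)
        prev = hz_from_cam(cam_from_hz(sig.f_sig_hz) - 4.0)
        prev_cam = cam_from_hz(prev)
        for _ in range(2000):
            stim, _, _ = select_next_stimulus(prior, cand, 18.0, prev, rng,
                                              sig, sloping_audiogram)
            assert abs(cam_from_hz(stim.f_mask_hz) - prev_cam) >= 2.0

    def test_selection_frequencies_match_weights(self, sloping_audiogram):
        """Chi-square check of empirical draw frequencies against the
        independently computed MI x Gaussian weights (1e5 draws)."""
        sig = SignalSpec(2000.0, 80.0)
        prior = build_prior(sloping_audiogram, sig)
        cand = CandidateGrid.for_signal(sig, cam_step=1.0, level_step_db=10.0)
        fe_hat = cam_from_hz(sig.f_sig_hz) - 1.5
        prev = None

        mi = np.array([
            mutual_information(prior, Stimulus(f, l), sig, sloping_audiogram)
            for f, l in zip(cand.f_mask_hz, cand.l_mask_db)
        ])
        expected = mi * np.exp(-0.5 * ((cand.f_mask_cam - fe_hat) / 1.5) ** 2)
        expected /= expected.sum()

        weights, fell_back = _selection_weights(mi, cand, fe_hat, prev, 1.5, 2.0)
        assert not fell_back
        np.testing.assert_allclose(weights, expected, atol=1e-12)

        rng = np.random.default_rng(12345)
        n = 100_000
        draws = rng.choice(cand.n, size=n, p=weights)
        counts = np.bincount(draws, minlength=cand.n)
        keep = expected * n >= 5  # chi-square validity
        stat, pval = chisquare(counts[keep], expected[keep] / expected[keep].sum() * counts[keep].sum())
        assert pval > 0.01

    def test_zero_weights_fall_back_to_uniform(self):
        cand = CandidateGrid.for_signal(SignalSpec(2000.0, 80.0),
                                        cam_step=2.0, level_step_db=35.0)
        mi = np.zeros(cand.n)
        w, fell_back = _selection_weights(mi, cand, 18.0, None, 1.5, 2.0)
        assert fell_back
        np.testing.assert_allclose(w, np.full(cand.n, 1.0 / cand.n))


class TestStopping:
    @pytest.mark.parametrize(
        "trace, expected",
        [
            ((0.05, 0.04, 0.03), True),
            ((0.05, 0.2, 0.03), False),
            ((0.04, 0.03), False),
            ((0.5, 0.05, 0.04, 0.03), True),
        ],
    )
    def test_three_consecutive_quiet_trials(self, trace, expected):
        assert stopping_check(list(trace), 0.1) is expected


class TestSession:
    def test_trial_counts_and_phases(self, session0):
        trials = session0.trials
        assert len(trials) == 124
        assert sum(t.is_practice for t in trials) == 4
        assert sum(t.is_catch for t in trials) == 20
        grid = [t for t in trials if t.phase == "initial_grid"]
        active = [t for t in trials if t.phase == "active" and not t.is_catch]
        assert len(grid) == 16
        assert len(active) == 84
        assert len(session0.fe_map_trace) == 100
        assert len(session0.mi_trace) == 84

    def test_determinism_bit_identical(self, listener0, signal0):
        cfg = SessionConfig(rng_seed=42)
        a = listener0.profile.audiogram
        r1 = run_session(cfg, listener0, a, signal0)
        r2 = run_session(cfg, listener0, a, signal0)
        assert r1.trials == r2.trials
        assert r1.final_fe_cam == r2.final_fe_cam
        assert r1.mi_trace == r2.mi_trace

    def test_mi_trace_declines_in_trend(self, session0):
        mi = session0.mi_trace
        assert np.mean(mi[40:50]) < np.mean(mi[:10])

    def test_maskers_cluster_near_true_edge(self, session0, listener0):
        true_cam = cam_from_hz(listener0.profile.true_fe_hz)
        active = [t for t in session0.trials
                  if t.phase == "active" and not t.is_catch]
        dev = [abs(cam_from_hz(t.x.f_mask_hz) - true_cam) for t in active]
        assert np.median(dev) < 3.0

    def test_recovery_survives_without_gaussian_weighting(self, listener0, signal0):
        """The f_e weighting is an efficiency device: removing it (sigma ->
        infinity) must not break recovery."""
        cfg = SessionConfig(rng_seed=3, weight_sigma_cam=1e9)
        res = run_session(cfg, listener0, listener0.profile.audiogram, signal0)
        true_cam = cam_from_hz(listener0.profile.true_fe_hz)
        assert abs(res.fe_map_trace[-1] - true_cam) <= 0.5

    def test_early_stop_requires_three_quiet_trials(self, listener0, signal0):
        cfg = SessionConfig(rng_seed=11, enable_early_stop=True,
                            stop_mi_threshold_bits=0.1)
        res = run_session(cfg, listener0, listener0.profile.audiogram, signal0)
        assert any(f.startswith("early_stop") for f in res.flags)
        assert all(m < 0.1 for m in res.mi_trace[-3:])
        assert len(res.trials) < 124

    def test_adaptive_sd_floors_at_two_db(self, listener0, signal0):
        cfg = SessionConfig(rng_seed=11, adaptive_sd=True)
        res = run_session(cfg, listener0, listener0.profile.audiogram, signal0)
        assert all(sd >= 2.0 for sd in res.sd_trace)
        assert res.sd_trace[0] == 3.0  # starts at the nominal slope

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_catch"):
            SessionConfig(n_active_trials=20, n_catch=15)
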
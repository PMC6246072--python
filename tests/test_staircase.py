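import numpy as np
import pytest

from binratio import (
    PsychometricListener,
    ha_disadvantage_measured,
    respond,
    run_track,
    srm,
)
from binratio.staircase import fit_threshold


class TestListener:
    def test_midpoint_probability_half(self):
        listener = PsychometricListener(true_srt=-10.0, slope=0.15, lapse=0.0)
        assert listener.p_correct(-10.0) == pytest.approx(0.5)

    def test_asymptote_respects_lapse(self):
        listener = PsychometricListener(true_srt=-10.0, slope=0.15, lapse=0.05)
        assert listener.p_correct(100.0) == pytest.approx(0.95, abs=1e-6)

    def test_midpoint_proportion_from_many_draws(self):
        listener = PsychometricListener(true_srt=-10.0, slope=0.15)
        rng = np.random.default_rng(0)
        hits = sum(respond(listener, -10.0, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.015)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PsychometricListener(0.0, slope=-0.1)
        with pytest.raises(ValueError):
            PsychometricListener(0.0, slope=0.1, lapse=0.5)


class TestTrack:
    def test_levels_form_a_lattice(self):
        listener = PsychometricListener(true_srt=-8.0, slope=0.2)
        track = run_track(listener, start_level=0.0, step=2.0, seed=5)
        offsets = (track.levels - 0.0) / 2.0
        assert np.allclose(offsets, np.round(offsets))

    def test_one_up_one_down_rule(self):
        listener = PsychometricListener(true_srt=-8.0, slope=0.2)
        track = run_track(listener, start_level=0.0, step=2.0, seed=6)
        for i in range(len(track.levels) - 1):
            expected = track.levels[i] + (-2.0 if track.responses[i] else 2.0)
            assert track.levels[i + 1] == expected

    def test_trial_count_bounds_and_se_rule(self):
        listener = PsychometricListener(true_srt=-12.0, slope=0.15)
        for seed in range(25):
            track = run_track(listener, start_level=0.0, step=2.0, seed=seed)
            assert 16 <= track.n_trials <= 32
            if track.n_trials < 32:
                assert track.standard_error < 0.8

    def test_deterministic_step_listener_recovered(self):
        """A near-step psychometric at -10 dB is recovered within 1 dB."""
        listener = PsychometricListener(true_srt=-10.0, slope=50.0)
        track = run_track(listener, 0.0, 2.0, seed=1, assumed_slope=0.15)
        assert track.estimate == pytest.approx(-10.0, abs=1.0)
        # descent phase is monotone while responses stay correct
        first_wrong = int(np.argmin(track.responses))
        assert np.all(np.diff(track.levels[: first_wrong + 1]) == -2.0)

    def test_monte_carlo_recovery(self):
        listener = PsychometricListener(true_srt=-12.0, slope=0.15)
        estimates = [
            run_track(listener, 0.0, 2.0, seed=s).estimate for s in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(-12.0, abs=0.5)

    def test_se_shrinks_with_more_trials(self):
        """Estimator consistency: more trials give smaller threshold SE."""
        listener = PsychometricListener(true_srt=-10.0, slope=0.2)
        short = [
            run_track(listener, 0.0, 2.0, seed=s, min_trials=16, max_trials=16,
                      se_target=0.0).standard_error
            for s in range(30)
        ]
        long = [
            run_track(listener, 0.0, 2.0, seed=s, min_trials=64, max_trials=64,
                      se_target=0.0).standard_error
            for s in range(30)
        ]
        assert np.mean(long) < np.mean(short)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            run_track(PsychometricListener(-10.0), 0.0, step=0.0, seed=0)

    def test_fit_threshold_recovers_logistic_data(self):
        rng = np.random.default_rng(7)
        levels = rng.uniform(-16.0, -4.0, size=400)
        k = 4 * 0.15
        p = 1 / (1 + np.exp(-k * (levels - (-10.0))))
        responses = rng.random(400) < p
        theta, se = fit_threshold(levels, responses, slope=0.15)
        assert theta == pytest.approx(-10.0, abs=0.8)
        assert 0.0 < se < 1.0


class TestDefinitions:
    def test_srm_printed_arithmetic(self):
        assert srm(-12.0, -4.0) == 8.0
        assert srm(-9.8, -7.4) == pytest.approx(2.4)
        assert srm(-5.0, -5.0) == 0.0

    def test_ha_disadvantage_printed_arithmetic(self):
        assert ha_disadvantage_measured(-9.5, -12.0) == 2.5
        assert ha_disadvantage_measured(-7.8, -9.8) == pytest.approx(2.0)
        assert ha_disadvantage_measured(-6.0, -6.0) == 0.0
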
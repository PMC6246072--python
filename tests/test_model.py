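import math

import numpy as np
import pytest

from binratio import (
    BinauralSignal,
    EcParameters,
    FrameGrid,
    ModelConfig,
    MonoSignal,
    average_target,
    better_ear,
    binaural_unmasking,
    bmld_factor,
    design_gammatone_bank,
    ha_disadvantage,
    integrate,
    long_term_model,
    predict_condition,
    predicted_srm,
    target_stats,
)
from binratio.model import TargetStats
from binratio.stats import FrameStats
from tests.conftest import white


def make_target_stats(centers, pl, pr, phase=None):
    n = len(centers)
    return TargetStats(
        center_frequencies=np.asarray(centers, float),
        power_left=np.full(n, pl, float) if np.isscalar(pl) else np.asarray(pl),
        power_right=np.full(n, pr, float) if np.isscalar(pr) else np.asarray(pr),
        phase=np.zeros(n) if phase is None else np.asarray(phase),
    )


def make_frame_stats(centers, pl, pr, phase=0.0, coherence=1.0, n_frames=1):
    n = len(centers)
    shape = (n, n_frames)
    return FrameStats(
        center_frequencies=np.asarray(centers, float),
        power_left=np.full(shape, pl, float),
        power_right=np.full(shape, pr, float),
        phase=np.full(shape, phase, float),
        coherence=np.full(shape, coherence, float),
        valid=np.ones(shape, bool),
    )


class TestBetterEar:
    centers = [500.0, 1000.0]

    def test_ceiling_caps_quiet_interferer(self):
        ts = make_target_stats(self.centers, 1.0, 0.25)
        fs = make_frame_stats(self.centers, 0.01, 0.25)
        be = better_ear(ts, fs, ceiling_db=20.0)
        assert np.allclose(be, 20.0)  # left ear at exactly the ceiling

    def test_cap_from_30_db(self):
        ts = make_target_stats(self.centers, 1.0, 0.25)
        fs = make_frame_stats(self.centers, 0.001, 0.25)
        assert np.allclose(better_ear(ts, fs, 20.0), 20.0)

    def test_equal_powers_zero_db(self):
        ts = make_target_stats(self.centers, 0.3, 0.3)
        fs = make_frame_stats(self.centers, 0.3, 0.3)
        assert np.allclose(better_ear(ts, fs, 20.0), 0.0)

    def test_silent_interferer_both_ears_gets_ceiling(self):
        ts = make_target_stats(self.centers, 1.0, 1.0)
        fs = make_frame_stats(self.centers, 0.0, 0.0)
        assert np.allclose(better_ear(ts, fs, 20.0), 20.0)

    def test_silent_target_is_minus_infinity(self):
        ts = make_target_stats(self.centers, 0.0, 0.0)
        fs = make_frame_stats(self.centers, 0.5, 0.5)
        assert np.all(np.isneginf(better_ear(ts, fs, 20.0)))

    def test_bank_mismatch_rejected(self):
        ts = make_target_stats([500.0], 1.0, 1.0)
        fs = make_frame_stats(self.centers, 1.0, 1.0)
        with pytest.raises(ValueError):
            better_ear(ts, fs)


class TestBinauralUnmasking:
    def test_worked_point_500hz_antiphase(self):
        """Antiphasic target in a coherent masker at 500 Hz: 10.73 dB."""
        ts = make_target_stats([500.0], 1.0, 1.0, phase=[np.pi])
        fs = make_frame_stats([500.0], 1.0, 1.0, phase=0.0, coherence=1.0)
        bu = binaural_unmasking(ts, fs, EcParameters())
        assert bu[0, 0] == pytest.approx(10.73, abs=0.005)
        # and the EC factor itself
        assert bmld_factor(np.array([500.0]), EcParameters())[0] == pytest.approx(
            1.18464, abs=1e-5
        )

    def test_matched_phases_full_coherence_is_zero(self):
        ts = make_target_stats([500.0], 1.0, 1.0, phase=[0.7])
        fs = make_frame_stats([500.0], 1.0, 1.0, phase=0.7, coherence=1.0)
        assert binaural_unmasking(ts, fs)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_interferer_power_at_one_ear_gives_zero(self):
        ts = make_target_stats([500.0], 1.0, 1.0, phase=[np.pi])
        fs = make_frame_stats([500.0], 0.0, 1.0, phase=0.0, coherence=1.0)
        assert binaural_unmasking(ts, fs)[0, 0] == 0.0

    def test_invalid_coherence_rejected(self):
        ts = make_target_stats([500.0], 1.0, 1.0)
        fs = make_frame_stats([500.0], 1.0, 1.0, coherence=1.5)
        with pytest.raises(ValueError):
            binaural_unmasking(ts, fs)

    def test_brute_force_oracle_equivalence(self):
        """Vectorized BU matches scalar-math evaluation on random tuples."""
        rng = np.random.default_rng(99)
        ec = EcParameters(floor_at_zero=False)
        for _ in range(1000):
            f = rng.uniform(80.0, 10_000.0)
            phi_t = rng.uniform(-np.pi, np.pi)
            phi_i = rng.uniform(-np.pi, np.pi)
            rho = rng.uniform(0.0, 1.0)
            ts = make_target_stats([f], 1.0, 1.0, phase=[phi_t])
            fs = make_frame_stats([f], 1.0, 1.0, phase=phi_i, coherence=rho)
            got = binaural_unmasking(ts, fs, ec)[0, 0]
            # independent scalar evaluation of the closed form
            k = (1.0 + 0.25**2) * math.exp((2 * math.pi * f * 105e-6) ** 2)
            want = 10.0 * math.log10((k - math.cos(phi_t - phi_i)) / (k - rho))
            assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_to_common_phase_offset(self):
        """BU depends on the target-interferer phase difference only."""
        rng = np.random.default_rng(3)
        for offset in rng.uniform(-np.pi, np.pi, size=5):
            ts1 = make_target_stats([700.0], 1.0, 1.0, phase=[0.4])
            fs1 = make_frame_stats([700.0], 1.0, 1.0, phase=1.1, coherence=0.9)
            ts2 = make_target_stats([700.0], 1.0, 1.0, phase=[0.4 + offset])
            fs2 = make_frame_stats([700.0], 1.0, 1.0, phase=1.1 + offset, coherence=0.9)
            assert binaural_unmasking(ts1, fs1)[0, 0] == pytest.approx(
                binaural_unmasking(ts2, fs2)[0, 0], abs=1e-9
            )

    def test_floor_at_zero(self):
        ts = make_target_stats([500.0], 1.0, 1.0, phase=[0.0])
        fs = make_frame_stats([500.0], 1.0, 1.0, phase=0.0, coherence=0.5)
        assert binaural_unmasking(ts, fs, EcParameters(floor_at_zero=True))[0, 0] == 0.0
        unfloored = binaural_unmasking(ts, fs, EcParameters(floor_at_zero=False))
        assert unfloored[0, 0] < 0.0


class TestIntegration:
    def test_constant_components_add(self):
        bank = design_gammatone_bank(100.0, 7000.0, 1.0)
        cfg = ModelConfig(bank=bank, weighting="uniform")
        be = np.full((bank.n_bands, 4), 3.0)
        bu = np.full((bank.n_bands, 4), 1.5)
        out = integrate(be, bu, cfg)
        assert out.binaural_ratio_db == pytest.approx(4.5, abs=1e-12)
        assert out.better_ear_component_db == pytest.approx(3.0, abs=1e-12)
        assert out.binaural_unmasking_component_db == pytest.approx(1.5, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        bank = design_gammatone_bank(100.0, 7000.0, 1.0)
        cfg = ModelConfig(bank=bank)
        with pytest.raises(ValueError):
            integrate(np.zeros((3, 2)), np.zeros((3, 2)), cfg)

    def test_weights_normalized(self):
        bank = design_gammatone_bank(80.0, 10_000.0, 2.0)
        for weighting in ("sii", "uniform"):
            cfg = ModelConfig(bank=bank, weighting=weighting)
            w = cfg.weights()
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)


class TestAverageTarget:
    def test_two_identical_sentences(self):
        rate = 16000.0
        s = white(1.0, rate, seed=1)
        out = average_target([s, s], collocated_masker_rms=0.2, skip=0.1)
        trimmed = MonoSignal(s.samples[int(0.1 * rate):], rate).with_rms(0.2)
        assert np.allclose(out.samples, trimmed.samples)

    def test_output_length_is_min_minus_skip(self):
        rate = 16000.0
        sentences = [white(d, rate, seed=i) for i, d in enumerate((1.0, 1.2, 1.5))]
        out = average_target(sentences, collocated_masker_rms=0.1, skip=0.68)
        assert len(out) == int(1.0 * rate) - int(0.68 * rate)

    def test_rms_equalized(self):
        sentences = [white(1.0, 16000.0, seed=i) for i in range(3)]
        out = average_target(sentences, collocated_masker_rms=0.37)
        assert out.rms() == pytest.approx(0.37, rel=1e-9)

    def test_short_sentence_rejected(self):
        rate = 16000.0
        with pytest.raises(ValueError):
            average_target([white(0.5, rate), white(1.0, rate)], 0.1, skip=0.68)
        with pytest.raises(ValueError):
            average_target([white(1.0, rate)], 0.1)


class TestTargetStats:
    def test_diotic_target_zero_phase(self, small_bank):
        x = white(1.0, 16000.0, seed=6)
        ts = target_stats(BinauralSignal(x, x), small_bank)
        assert np.allclose(ts.phase, 0.0, atol=1e-9)

    def test_doubling_amplitude_quadruples_power(self, small_bank):
        x = white(1.0, 16000.0, seed=6)
        y = white(1.0, 16000.0, seed=8)
        base = target_stats(BinauralSignal(x, y), small_bank)
        loud = target_stats(BinauralSignal(x.scaled(2.0), y.scaled(2.0)), small_bank)
        assert np.allclose(loud.power_left, 4.0 * base.power_left, rtol=1e-9)
        assert np.allclose(loud.phase, base.phase, atol=1e-9)

    def test_silent_target_rejected(self, small_bank):
        silent = MonoSignal(np.zeros(16000), 16000.0)
        with pytest.raises(ValueError):
            target_stats(BinauralSignal(silent, silent), small_bank)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig(
        bank=design_gammatone_bank(100.0, 7000.0, 1.0), masker_duration=10.0
    )


@pytest.fixture(scope="module")
def diotic_scene():
    rate = 16000.0
    t = white(2.0, rate, seed=20)
    i = white(10.0, rate, seed=21)
    return BinauralSignal(t, t), BinauralSignal(i, i)


class TestEndToEnd:
    def test_collocated_diotic_bu_null(self, cfg, diotic_scene):
        target, interferer = diotic_scene
        out = predict_condition(target, interferer, cfg)
        assert abs(out.binaural_unmasking_component_db) < 0.1

    def test_ceiling_never_exceeded(self, cfg, diotic_scene):
        target, interferer = diotic_scene
        out = predict_condition(target, interferer, cfg)
        assert np.all(out.better_ear_db <= cfg.ceiling_db + 1e-12)

    def test_doubling_interferer_level_costs_6_db(self, cfg, diotic_scene):
        target, interferer = diotic_scene
        base = predict_condition(target, interferer, cfg)
        doubled = predict_condition(target, interferer.scaled(2.0), cfg)
        assert base.binaural_ratio_db - doubled.binaural_ratio_db == pytest.approx(
            6.02, abs=0.3
        )

    def test_itd_only_lateral_interferer_unmasks_low_bands(self, cfg):
        """An interferer lateralized purely by ITD yields BU > 0 below 1.5 kHz."""
        rate = 16000.0
        t = white(2.0, rate, seed=30)
        i = white(10.0, rate, seed=31).samples
        shift = int(round(6.5e-4 * rate))  # ~90 deg Woodworth delay
        interferer = BinauralSignal.from_arrays(i[shift:], i[:-shift], rate)
        target = BinauralSignal(t, t)
        out = predict_condition(target, interferer, cfg)
        low = cfg.bank.center_frequencies < 1500.0
        assert np.mean(out.binaural_unmasking_db[low]) > 0.5

    def test_long_term_deterministic(self, cfg, diotic_scene):
        target, interferer = diotic_scene
        a = long_term_model(target, interferer, cfg)
        b = long_term_model(target, interferer, cfg)
        assert a.binaural_ratio_db == b.binaural_ratio_db

    def test_dip_listening_grows_with_modulation_depth(self, cfg):
        """Short-term minus long-term ratio increases with modulation depth."""
        rate = 16000.0
        t = white(2.0, rate, seed=40)
        target = BinauralSignal(t, t)
        carrier = white(10.0, rate, seed=41).samples
        tt = np.arange(len(carrier)) / rate
        gaps = []
        for depth in (0.0, 0.5, 1.0):
            env = 1.0 - depth / 2 + depth / 2 * np.sin(2 * np.pi * 4.0 * tt)
            masker = BinauralSignal.from_arrays(carrier * env, carrier * env, rate)
            st = predict_condition(target, masker, cfg)
            lt = long_term_model(target, masker, cfg)
            gaps.append(st.binaural_ratio_db - lt.binaural_ratio_db)
        assert gaps[0] < gaps[1] < gaps[2]
        assert gaps[2] > 1.0  # full modulation gives a clear glimpsing benefit


class TestDerivedQuantities:
    def make_output(self, ratio):
        bank = design_gammatone_bank(100.0, 7000.0, 1.0)
        cfg = ModelConfig(bank=bank, weighting="uniform")
        be = np.full((bank.n_bands, 2), ratio)
        return integrate(be, np.zeros_like(be), cfg)

    def test_ha_disadvantage_definition(self):
        unaided = self.make_output(3.0)
        aided = self.make_output(1.5)
        assert ha_disadvantage(aided, unaided) == pytest.approx(1.5)
        assert ha_disadvantage(unaided, unaided) == 0.0

    def test_predicted_srm_definition_and_decomposition(self):
        separated = self.make_output(5.0)
        collocated = self.make_output(2.0)
        assert predicted_srm(separated, collocated) == pytest.approx(3.0)
        # SRM decomposes exactly into BE and BU parts
        srm_be = separated.better_ear_component_db - collocated.better_ear_component_db
        srm_bu = (
            separated.binaural_unmasking_component_db
            - collocated.binaural_unmasking_component_db
        )
        assert predicted_srm(separated, collocated) == pytest.approx(srm_be + srm_bu)
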
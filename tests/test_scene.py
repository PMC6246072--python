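import numpy as np
import pytest

from binratio import (
    BinauralSignal,
    Brir,
    MonoSignal,
    SceneConfig,
    condition_brirs,
    read_brir_bundle,
    render_scene,
    write_brir_bundle,
)
from tests.conftest import white


def make_brir(azimuth, rate=16000.0, duration=0.4, scale=(1.0, 1.0), aided=False):
    n = int(duration * rate)
    left = np.zeros(n)
    right = np.zeros(n)
    left[10] = scale[0]
    right[10] = scale[1]
    return Brir(
        response=BinauralSignal.from_arrays(left, right, rate),
        azimuth=azimuth,
        distance=1.3,
        aided=aided,
    )


def test_conditioning_truncates_to_300_ms():
    brirs = [make_brir(0.0, duration=0.4)]
    out = condition_brirs(brirs, white(2.0, 16000.0))
    assert len(out[0].response) == int(0.3 * 16000)


def test_conditioning_balances_doubled_right_ear():
    """Right ear at twice the left everywhere -> 0.5 correction on right."""
    brirs = [make_brir(0.0, scale=(1.0, 2.0)), make_brir(90.0, scale=(1.0, 2.0))]
    out = condition_brirs(brirs, white(2.0, 16000.0))
    for brir in out:
        ratio = np.max(np.abs(brir.response.right.samples)) / np.max(
            np.abs(brir.response.left.samples)
        )
        assert ratio == pytest.approx(1.0, rel=1e-9)


def test_conditioning_identity_for_balanced_set():
    brirs = [make_brir(0.0)]
    out = condition_brirs(brirs, white(2.0, 16000.0))
    assert np.max(np.abs(out[0].response.right.samples)) == pytest.approx(
        1.0, abs=1e-6
    )


def test_conditioning_requires_frontal_brir():
    with pytest.raises(ValueError):
        condition_brirs([make_brir(90.0)], white(1.0, 16000.0))


def test_render_identity_brir_passes_signals_through():
    rate = 16000.0
    n = int(0.1 * rate)
    impulse = np.zeros(n)
    impulse[0] = 1.0
    brir = Brir(
        response=BinauralSignal.from_arrays(impulse, impulse, rate),
        azimuth=0.0,
        distance=1.0,
    )
    target = white(0.5, rate, seed=1)
    masker = white(0.5, rate, seed=2)
    rendering = render_scene(brir, [brir], target, [masker], calibrate=False)
    assert np.allclose(rendering.target_ears.left.samples, target.samples)
    assert np.allclose(rendering.interferer_ears.right.samples, masker.samples)


def test_render_rejects_mismatched_masker_brirs():
    brir = make_brir(0.0)
    with pytest.raises(ValueError):
        render_scene(brir, [brir], white(0.5, 16000.0), [white(0.5, 16000.0)] * 2)


def test_collocated_sum_matches_direct_summation_oracle(rng):
    """Three maskers through one BRIR = sum of individual renderings."""
    import scipy.signal as sps

    rate = 16000.0
    brir = make_brir(0.0, scale=(0.8, 1.1))
    maskers = [white(0.5, rate, seed=s) for s in (1, 2, 3)]
    rendering = render_scene(brir, [brir] * 3, white(0.5, rate, seed=9), maskers,
                             calibrate=False)
    n = len(maskers[0])
    expected = sum(
        sps.fftconvolve(m.samples, brir.response.left.samples)[:n] for m in maskers
    )
    assert np.allclose(rendering.interferer_ears.left.samples, expected, atol=1e-12)


def test_aided_scene_attenuates_feeds_10_db():
    rate = 16000.0
    brir = make_brir(0.0)
    target = white(0.5, rate, seed=4)
    cfg_unaided = SceneConfig(rate=rate, aided=False)
    cfg_aided = SceneConfig(rate=rate, aided=True)
    plain = render_scene(brir, [brir], target, [target], cfg_unaided, calibrate=False)
    attenuated = render_scene(brir, [brir], target, [target], cfg_aided, calibrate=False)
    gain = 20 * np.log10(
        attenuated.target_ears.left.rms() / plain.target_ears.left.rms()
    )
    assert gain == pytest.approx(-10.0, abs=0.01)


def test_masker_calibration_equalizes_a_weighted_power():
    from binratio.scene import a_weighted_rms

    rate = 16000.0
    brir = make_brir(0.0)
    loud = white(0.5, rate, seed=5).scaled(10.0)
    quiet = white(0.5, rate, seed=6).scaled(0.1)
    rendering = render_scene(brir, [brir, brir], white(0.5, rate, seed=7),
                             [loud, quiet], calibrate=True)
    # after calibration both maskers contribute equally: the sum's power is
    # twice a single calibrated masker's power (independent noises)
    assert rendering.interferer_ears.left.rms() > 0


def test_brir_bundle_roundtrip(tmp_path):
    brirs = [make_brir(0.0), make_brir(90.0, aided=True)]
    write_brir_bundle(tmp_path / "bundle", brirs, meta={"seed": 1})
    back = read_brir_bundle(tmp_path / "bundle")
    assert len(back) == 2
    assert back[1].azimuth == 90.0
    assert back[1].aided is True
    assert np.allclose(
        back[0].response.left.samples, brirs[0].response.left.samples, atol=1e-7
    )
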
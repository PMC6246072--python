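"""BRIR conditioning and scene rendering.

Mirrors the measurement-side processing applied to a BRIR set before any
analysis: truncation to 300 ms, a single left/right balance correction
derived from the speech-weighted direct sound of the frontal response, and
the convolution of target/masker stimuli with their BRIRs into the two ear
signals the intelligibility model consumes (target ears, and the sum of all
interferer ears).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .rooms import Brir, SceneConfig
from .signal import BinauralSignal, MonoSignal, read_wav, write_wav

BRIR_TRUNCATION = 0.300  # seconds
DIRECT_SOUND_WINDOW = 0.00385  # seconds: direct sound before first reflection
MASKER_REFERENCE_DBFS = -25.0  # per-scene total masker level re full scale


def _truncate(brir: Brir, duration: float) -> Brir:
    n = int(round(duration * brir.rate))
    if len(brir.response) <= n:
        return brir
    return Brir(
        response=BinauralSignal.from_arrays(
            brir.response.left.samples[:n],
            brir.response.right.samples[:n],
            brir.rate,
        ),
        azimuth=brir.azimuth,
        distance=brir.distance,
        aided=brir.aided,
    )


def _speech_weighted(samples: np.ndarray, reference: MonoSignal, rate: float) -> np.ndarray:
    """Filter a snippet with the long-term magnitude spectrum of a reference."""
    nfft = int(2 ** np.ceil(np.log2(4 * len(samples))))
    freqs, psd = sps.welch(
        reference.samples, fs=reference.rate, nperseg=min(len(reference), 4096)
    )
    magnitude = np.interp(np.fft.rfftfreq(nfft, 1.0 / rate), freqs, np.sqrt(psd))
    return np.fft.irfft(np.fft.rfft(samples, nfft) * magnitude, nfft)[: len(samples)]


def condition_brirs(
    brirs: list[Brir],
    target_reference: MonoSignal,
    truncation: float = BRIR_TRUNCATION,
) -> list[Brir]:
    """Truncate a BRIR set and balance the ears on the frontal direct sound.

    The first 3.85 ms of the frontal (0°) response — the direct sound before
    the first room reflection — is filtered with the long-term magnitude
    spectrum of the target reference; the scalar that equalizes the two
    ears' RMS over that window is then applied to the right ear of *every*
    BRIR in the set.
    """
    frontal = next((b for b in brirs if b.azimuth == 0.0), None)
    if frontal is None:
        raise ValueError("BRIR set must contain the frontal (0 deg) response")
    truncated = [_truncate(b, truncation) for b in brirs]
    frontal = next(b for b in truncated if b.azimuth == 0.0)
    n_direct = int(round(DIRECT_SOUND_WINDOW * frontal.rate))
    weighted_l = _speech_weighted(
        frontal.response.left.samples[:n_direct], target_reference, frontal.rate
    )
    weighted_r = _speech_weighted(
        frontal.response.right.samples[:n_direct], target_reference, frontal.rate
    )
    rms_l = np.sqrt(np.mean(weighted_l**2))
    rms_r = np.sqrt(np.mean(weighted_r**2))
    if rms_r == 0:
        raise ValueError("frontal right-ear direct sound is silent")
    correction = rms_l / rms_r
    return [b.scaled(1.0, correction) for b in truncated]


def a_weighting_db(freqs: np.ndarray) -> np.ndarray:
    """IEC 61672 A-weighting in dB at the given frequencies (Hz)."""
    f2 = np.square(np.maximum(freqs, 1e-6))
    ra = (
        12194.0**2
        * f2**2
        / (
            (f2 + 20.6**2)
            * np.sqrt((f2 + 107.7**2) * (f2 + 737.9**2))
            * (f2 + 12194.0**2)
        )
    )
    return 20.0 * np.log10(ra) + 2.0


def a_weighted_rms(x: MonoSignal) -> float:
    """RMS of the signal after A-weighting (frequency-domain)."""
    spec = np.fft.rfft(x.samples)
    freqs = np.fft.rfftfreq(len(x), 1.0 / x.rate)
    gains = 10.0 ** (a_weighting_db(freqs) / 20.0)
    energy = np.sum(np.abs(spec * gains) ** 2) / len(x)
    return float(np.sqrt(energy / len(x)) * np.sqrt(2.0))


@dataclass(frozen=True)
class SceneRendering:
    """The model's two inputs: target ears and summed-interferer ears."""

    target_ears: BinauralSignal
    interferer_ears: BinauralSignal


def _convolve(signal: MonoSignal, brir: Brir) -> BinauralSignal:
    if signal.rate != brir.rate:
        raise ValueError("stimulus and BRIR sampling rates differ")
    left = sps.fftconvolve(signal.samples, brir.response.left.samples)[: len(signal)]
    right = sps.fftconvolve(signal.samples, brir.response.right.samples)[: len(signal)]
    return BinauralSignal.from_arrays(left, right, signal.rate)


def render_scene(
    target_brir: Brir,
    masker_brirs: list[Brir],
    target: MonoSignal,
    maskers: list[MonoSignal],
    cfg: SceneConfig | None = None,
    calibrate: bool = True,
) -> SceneRendering:
    """Convolve stimuli with their BRIRs into the model's two inputs.

    Each masker feed is calibrated to equal A-weighted power, with the total
    masker level at the fixed scene reference; in aided scenes every
    loudspeaker feed is attenuated by the configured playback attenuation
    (the insertion gain lives in the aided BRIRs).
    """
    if len(masker_brirs) != len(maskers):
        raise ValueError(
            f"{len(maskers)} maskers but {len(masker_brirs)} masker BRIRs"
        )
    feed_gain = 1.0
    if cfg is not None and cfg.aided:
        feed_gain = 10.0 ** (-cfg.playback_attenuation_db / 20.0)

    if calibrate:
        per_masker = 10.0 ** (MASKER_REFERENCE_DBFS / 20.0) / np.sqrt(
            max(len(maskers), 1)
        )
        maskers = [m.scaled(per_masker / a_weighted_rms(m)) for m in maskers]

    target_ears = _convolve(target.scaled(feed_gain), target_brir)
    interferer = None
    for masker, brir in zip(maskers, masker_brirs):
        ears = _convolve(masker.scaled(feed_gain), brir)
        if interferer is None:
            interferer = ears.as_array()
        else:
            n = min(len(interferer), len(ears))
            interferer = interferer[:n] + ears.as_array()[:n]
    if interferer is None:
        raise ValueError("at least one masker is required")
    return SceneRendering(
        target_ears=target_ears,
        interferer_ears=BinauralSignal.from_arrays(
            interferer[:, 0], interferer[:, 1], target.rate
        ),
    )


# ---------------------------------------------------------------------------
# BRIR bundle I/O: one WAV per source plus a JSON sidecar
# ---------------------------------------------------------------------------

def write_brir_bundle(directory: str | Path, brirs: list[Brir], meta: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, brir in enumerate(brirs):
        name = f"brir_{i:02d}_az{int(round(brir.azimuth)):+04d}.wav"
        write_wav(directory / name, brir.response, subtype="float32")
        entries.append(
            {
                "file": name,
                "azimuth": brir.azimuth,
                "distance": brir.distance,
                "aided": brir.aided,
            }
        )
    sidecar = {"brirs": entries}
    if meta:
        sidecar["meta"] = meta
    (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))


def read_brir_bundle(directory: str | Path) -> list[Brir]:
    directory = Path(directory)
    sidecar = json.loads((directory / "bundle.json").read_text())
    brirs = []
    for entry in sidecar["brirs"]:
        response = read_wav(directory / entry["file"])
        if not isinstance(response, BinauralSignal):
            raise ValueError(f"{entry['file']} is not 2-channel")
        brirs.append(
            Brir(
                response=response,
                azimuth=entry["azimuth"],
                distance=entry["distance"],
                aided=entry["aided"],
            )
        )
    return brirs
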
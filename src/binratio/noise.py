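"""Masker and target stimulus generators.

Two synthetic stimulus families stand in for recorded speech material:

* stationary speech-shaped noise (SSN): Gaussian noise spectrally matched to
  a reference signal through a 2048-tap FIR difference filter;
* speech-like modulated noise: the same carrier multiplied by a slow
  (2–8 Hz) log-normal envelope so that it contains near-silent gaps for
  dip listening, while keeping the SSN long-term spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signal import MonoSignal

#: long-term speech spectrum approximation used when no recorded reference is
#: available: pink-ish below a 500-Hz knee, -8 dB/oct above (rough LTASS tilt)
_LTASS_KNEE_HZ = 500.0
_LTASS_SLOPE_DB_PER_OCT = -8.0


def speech_shaped_reference(
    duration: float, rate: float, seed: int | np.random.Generator = 0
) -> MonoSignal:
    """Generate a stand-in 'recorded talker' reference with a speech-like
    long-term spectrum (flat to a 500-Hz knee, then falling ~8 dB/octave).

    This is a synthetic surrogate for the interfering-talker recordings that
    anchor the SSN spectra; any long recording can be used instead.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    gain = np.ones_like(f)
    above = f > _LTASS_KNEE_HZ
    octaves = np.log2(f[above] / _LTASS_KNEE_HZ)
    gain[above] = 10.0 ** (_LTASS_SLOPE_DB_PER_OCT * octaves / 20.0)
    out = np.fft.irfft(spec * gain, n)
    return MonoSignal(out / np.std(out) * 0.05, rate)


def pink_reference(
    duration: float,
    rate: float,
    seed: int | np.random.Generator = 0,
    knee: float = 20.0,
) -> MonoSignal:
    """Band-limited pink noise (1/f power above ``knee`` Hz, flat below).

    The low-frequency knee keeps the power finite, as in any physical pink
    source; useful as a smooth wideband reference for spectral-matching
    checks.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    gain = 1.0 / np.sqrt(np.maximum(f, knee))
    out = np.fft.irfft(spec * gain, n)
    return MonoSignal(out / np.std(out) * 0.05, rate)


def _matching_fir(reference: MonoSignal, n_taps: int) -> np.ndarray:
    """Linear-phase FIR whose magnitude response matches the reference
    long-term magnitude spectrum (the 'difference filter' between white
    noise and the reference spectrum)."""
    nperseg = min(len(reference), 4 * n_taps)
    freqs, psd = sps.welch(reference.samples, fs=reference.rate, nperseg=nperseg)
    gains = np.sqrt(psd)
    gains /= np.max(gains)
    if n_taps % 2 == 0:  # Type II FIR needs a Nyquist null
        gains[-1] = 0.0
    # design on the (fine) Welch grid so steep low-frequency slopes survive
    return sps.firwin2(
        n_taps, freqs / (reference.rate / 2.0), gains, nfreqs=1 << 14 | 1
    )


def generate_ssn(
    reference: MonoSignal,
    duration: float,
    seed: int | np.random.Generator = 0,
    n_taps: int = 2048,
) -> MonoSignal:
    """Stationary speech-shaped noise matched to a reference spectrum.

    White Gaussian noise is convolved with an ``n_taps``-tap FIR filter
    derived from the reference's estimated magnitude spectrum; the output RMS
    is equalized to the reference RMS.
    """
    if n_taps <= 0:
        raise ValueError("n_taps must be positive")
    rng = np.random.default_rng(seed)
    fir = _matching_fir(reference, n_taps)
    n = int(round(duration * reference.rate))
    # generate extra samples so the filter transient can be discarded
    white = rng.standard_normal(n + n_taps)
    shaped = sps.fftconvolve(white, fir, mode="full")[n_taps : n_taps + n]
    return MonoSignal(shaped, reference.rate).with_rms(reference.rms())


def generate_speechlike(
    duration: float,
    rate: float,
    seed: int | np.random.Generator = 0,
    reference: MonoSignal | None = None,
    modulation_band: tuple[float, float] = (2.0, 6.0),
    modulation_strength: float = 1.2,
) -> MonoSignal:
    """Speech-like modulated masker: SSN carrier times a slow envelope.

    The envelope is ``exp(a * z)`` with ``z`` zero-mean unit-variance noise
    band-limited to ``modulation_band`` (Hz), giving a log-normal power
    envelope whose instantaneous level is Gaussian in dB with a standard
    deviation of ``8.686 * a`` dB.  The default ``a = 1.2`` (~10 dB level
    spread, comparable to running speech) leaves well over 5% of 12-ms
    frames more than 20 dB below the mean power, while keeping a
    realization's long-term spectrum within ~1 dB of the unmodulated SSN;
    the RMS is equalized to the unmodulated SSN exactly.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = speech_shaped_reference(20.0, rate, rng)
    ssn = generate_ssn(reference, duration, rng)
    n = len(ssn)
    lo, hi = modulation_band
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    z = sps.sosfilt(sos, rng.standard_normal(n))
    z /= np.std(z)
    envelope = np.exp(modulation_strength * z)
    out = MonoSignal(ssn.samples * envelope, rate)
    return out.with_rms(ssn.rms())
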
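"""Interaural statistics per gammatone band and time frame.

For every band (and frame, in short-term mode) this module measures the four
quantities the intelligibility model consumes: the power at each ear, the
interaural phase difference, and the interaural coherence.

Phase and coherence are computed from analytic band signals.  With
``cross = sum(l_a * conj(r_a))`` over the (tapered) frame,

* phase = arg(cross) — positive when the right ear lags the left;
* coherence = |cross| / sqrt(sum|l_a|^2 * sum|r_a|^2).

For narrowband gammatone outputs the coherence magnitude equals the maximum
of the normalized interaural cross-correlation within physiological lags
(±1 ms); the explicit lag search lives in :mod:`binratio.cues` where the lag
itself (the ITD) is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .framing import FrameGrid, frame_starts, frame_windowed_sums
from .gammatone import GammatoneBank, analytic_band_signals
from .signal import BinauralSignal

#: sentinel grid selecting one statistic over the whole signal
LONG_TERM = "long-term"


@dataclass(frozen=True)
class FrameStats:
    """Per-band(-frame) interaural statistics of a binaural signal.

    All arrays have shape ``(n_bands, n_frames)``; long-term statistics use
    ``n_frames == 1``.  Cells where both ears carry zero power are flagged
    ``valid == False`` (phase/coherence are undefined there; consumers
    decide, see the binaural-unmasking guard).
    """

    center_frequencies: np.ndarray
    power_left: np.ndarray
    power_right: np.ndarray
    phase: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.power_left.shape[0]

    @property
    def n_frames(self) -> int:
        return self.power_left.shape[1]


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


def interaural_stats(
    x: BinauralSignal,
    bank: GammatoneBank,
    grid: FrameGrid | str = LONG_TERM,
) -> FrameStats:
    """Measure per-band (and per-frame) powers, phase and coherence.

    ``grid`` may be a :class:`FrameGrid` for short-term statistics or the
    string ``"long-term"`` for one statistic over the whole signal
    (rectangular window).
    """
    n = len(x)
    rate = x.rate
    if isinstance(grid, str):
        if grid != LONG_TERM:
            raise ValueError(f"unknown grid {grid!r}")
        starts = np.array([0])
        weights = np.ones(n)
    else:
        starts = frame_starts(grid, n, rate)
        weights = grid.taper(rate)
    w2 = weights * weights
    w2_sum = float(np.sum(w2))  # power normalizer: unbiased for stationary input
    n_frames = len(starts)

    power_l = np.empty((bank.n_bands, n_frames))
    power_r = np.empty_like(power_l)
    phase = np.empty_like(power_l)
    coherence = np.empty_like(power_l)

    left_bands = analytic_band_signals(x.left, bank)
    right_bands = analytic_band_signals(x.right, bank)
    for (band, l_a), (_, r_a) in zip(left_bands, right_bands):
        re_l, re_r = l_a.real, r_a.real
        power_l[band] = frame_windowed_sums(re_l * re_l, w2, starts) / w2_sum
        power_r[band] = frame_windowed_sums(re_r * re_r, w2, starts) / w2_sum
        cross = frame_windowed_sums(l_a * np.conj(r_a), w2, starts)
        mag_l = frame_windowed_sums(np.abs(l_a) ** 2, w2, starts)
        mag_r = frame_windowed_sums(np.abs(r_a) ** 2, w2, starts)
        norm = np.sqrt(mag_l * mag_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(cross) / norm
        phase[band] = _wrap_phase(np.angle(cross))
        coherence[band] = np.clip(np.nan_to_num(coh, nan=1.0), 0.0, 1.0)

    valid = (power_l > 0) | (power_r > 0)
    phase[~valid] = 0.0
    coherence[~valid] = 1.0
    return FrameStats(
        center_frequencies=bank.center_frequencies,
        power_left=power_l,
        power_right=power_r,
        phase=phase,
        coherence=coherence,
        valid=valid,
    )
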
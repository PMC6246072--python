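"""Short-time framing: 24-ms half-overlapping Hann windows by default."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .signal import MonoSignal


@dataclass(frozen=True)
class FrameGrid:
    """Short-time analysis grid.

    frame_length : float
        Frame duration in seconds (default 24 ms).
    hop : float
        Frame advance in seconds; half the frame length (12 ms effective
        duration with the Hann taper).
    window : str
        Taper identifier understood by :func:`scipy.signal.get_window`.
    """

    frame_length: float = 0.024
    hop: float = 0.012
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.frame_length <= 0 or self.hop <= 0:
            raise ValueError("frame length and hop must be positive")

    @classmethod
    def halfoverlap(cls, frame_length: float = 0.024, window: str = "hann") -> "FrameGrid":
        return cls(frame_length=frame_length, hop=frame_length / 2, window=window)

    def frame_samples(self, rate: float) -> int:
        return int(round(self.frame_length * rate))

    def hop_samples(self, rate: float) -> int:
        return int(round(self.hop * rate))

    def n_frames(self, n_samples: int, rate: float) -> int:
        length = self.frame_samples(rate)
        hop = self.hop_samples(rate)
        if n_samples < length:
            raise ValueError(
                f"signal of {n_samples} samples shorter than one "
                f"{length}-sample frame"
            )
        return (n_samples - length) // hop + 1

    def taper(self, rate: float) -> np.ndarray:
        # periodic window, the standard choice for overlapped analysis
        return get_window(self.window, self.frame_samples(rate), fftbins=True)


def frame_starts(grid: FrameGrid, n_samples: int, rate: float) -> np.ndarray:
    """Start indices of the complete frames (trailing partial discarded)."""
    hop = grid.hop_samples(rate)
    return np.arange(grid.n_frames(n_samples, rate)) * hop


def frame_signal(x: MonoSignal, grid: FrameGrid) -> np.ndarray:
    """Slice a signal into tapered frames.

    Returns an ``(n_frames, frame_samples)`` array of Hann-windowed frames;
    the trailing partial frame is discarded.
    """
    length = grid.frame_samples(x.rate)
    starts = frame_starts(grid, len(x), x.rate)
    window = grid.taper(x.rate)
    frames = np.lib.stride_tricks.sliding_window_view(x.samples, length)[starts]
    return frames * window


def frame_windowed_sums(
    values: np.ndarray, weights: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Per-frame weighted sums: ``out[k] = sum(values[s_k : s_k+L] * weights)``.

    ``values`` may be real or complex; used to accumulate short-time powers
    and cross-power terms without materialising windowed frame copies per
    quantity.
    """
    view = np.lib.stride_tricks.sliding_window_view(values, len(weights))[starts]
    return view @ weights
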
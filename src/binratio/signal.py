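"""Signal containers and WAV input/output.

Two small dataclasses carry every waveform in the package: :class:`MonoSignal`
(one channel plus its sampling rate) and :class:`BinauralSignal` (a left/right
pair with matching length and rate).  Sampling-rate mismatches between signals
are treated as errors everywhere — nothing in the package resamples silently.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


class RateMismatchError(ValueError):
    """Raised when two signals with different sampling rates are combined."""


@dataclass(frozen=True)
class MonoSignal:
    """A single-channel sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Linear amplitude samples (dimensionless, float64).
    rate : float
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("MonoSignal samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("MonoSignal samples must be finite")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.rate

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, factor: float) -> "MonoSignal":
        return MonoSignal(self.samples * factor, self.rate)

    def with_rms(self, target_rms: float) -> "MonoSignal":
        """Return a copy scaled to the given RMS amplitude."""
        current = self.rms()
        if current == 0.0:
            raise ValueError("cannot set the RMS of a silent signal")
        return self.scaled(target_rms / current)


@dataclass(frozen=True)
class BinauralSignal:
    """A two-channel (left/right ear) waveform.

    Left and right must share length and sampling rate.
    """

    left: MonoSignal
    right: MonoSignal

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right channels must have equal length")
        if self.left.rate != self.right.rate:
            raise RateMismatchError(
                f"left rate {self.left.rate} != right rate {self.right.rate}"
            )

    @classmethod
    def from_arrays(
        cls, left: np.ndarray, right: np.ndarray, rate: float
    ) -> "BinauralSignal":
        return cls(MonoSignal(left, rate), MonoSignal(right, rate))

    @property
    def rate(self) -> float:
        return self.left.rate

    def __len__(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        return self.left.duration

    def as_array(self) -> np.ndarray:
        """Stack the two channels into an (n, 2) array."""
        return np.stack([self.left.samples, self.right.samples], axis=1)

    def scaled(self, factor: float) -> "BinauralSignal":
        return BinauralSignal(self.left.scaled(factor), self.right.scaled(factor))

    def swapped(self) -> "BinauralSignal":
        """Return the signal with the ears exchanged."""
        return BinauralSignal(self.right, self.left)


# ---------------------------------------------------------------------------
# WAV I/O.  scipy handles PCM 16/24/32 and float32/64 on read; on write it
# covers PCM16 and float32, and the 24-bit case is packed by hand below.
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31}


def read_wav(path: str | Path) -> MonoSignal | BinauralSignal:
    """Read a WAV file into a Mono- or BinauralSignal.

    Integer PCM data are rescaled to [-1, 1); float data pass through.
    """
    rate, data = wavfile.read(str(path))
    data = np.atleast_2d(data.T).T  # (n, channels)
    if data.dtype in _PCM_SCALE:
        data = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.shape[1] == 1:
        return MonoSignal(data[:, 0], float(rate))
    if data.shape[1] == 2:
        return BinauralSignal.from_arrays(data[:, 0], data[:, 1], float(rate))
    raise ValueError(f"expected 1 or 2 channels, got {data.shape[1]}")


def write_wav(
    path: str | Path,
    signal: MonoSignal | BinauralSignal,
    subtype: str = "float32",
) -> None:
    """Write a signal to WAV as ``float32``, ``pcm16`` or ``pcm24``."""
    if isinstance(signal, BinauralSignal):
        data = signal.as_array()
        rate = signal.rate
    else:
        data = signal.samples[:, None]
        rate = signal.rate
    rate = int(round(rate))
    if subtype == "float32":
        wavfile.write(str(path), rate, np.squeeze(data.astype(np.float32)))
    elif subtype == "pcm16":
        clipped = np.clip(data, -1.0, 1.0 - 2.0**-15)
        wavfile.write(
            str(path), rate, np.squeeze((clipped * 2.0**15).round().astype(np.int16))
        )
    elif subtype == "pcm24":
        _write_pcm24(Path(path), data, rate)
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")


def _write_pcm24(path: Path, data: np.ndarray, rate: int) -> None:
    """Minimal RIFF writer for 24-bit PCM (scipy cannot write it)."""
    clipped = np.clip(data, -1.0, 1.0 - 2.0**-23)
    ints = (clipped * 2.0**23).round().astype(np.int32)
    n, channels = ints.shape
    # little-endian 3-byte packing: drop the high byte of the int32
    raw = ints.astype("<i4").tobytes()
    frames = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    byte_rate = rate * channels * 3
    block_align = channels * 3
    with open(path, "wb") as fh:
        fh.write(b"RIFF")
        fh.write(struct.pack("<I", 36 + len(frames)))
        fh.write(b"WAVEfmt ")
        fh.write(
            struct.pack(
                "<IHHIIHH", 16, 1, channels, rate, byte_rate, block_align, 24
            )
        )
        fh.write(b"data")
        fh.write(struct.pack("<I", len(frames)))
        fh.write(frames)
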
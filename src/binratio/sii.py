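"""Speech-intelligibility-index band-importance weighting.

One-third-octave band-importance values (ANSI S3.5 style, 160 Hz – 8 kHz)
interpolated on a log-frequency axis to arbitrary gammatone centers and
renormalized to sum to one.  Centers outside the tabulated range get zero
importance before renormalization.
"""

from __future__ import annotations

import numpy as np

# (center frequency Hz, band importance) — standard 18-band 1/3-octave table
_THIRD_OCTAVE_IMPORTANCE = np.array(
    [
        (160.0, 0.0083),
        (200.0, 0.0095),
        (250.0, 0.0150),
        (315.0, 0.0289),
        (400.0, 0.0440),
        (500.0, 0.0578),
        (630.0, 0.0653),
        (800.0, 0.0711),
        (1000.0, 0.0818),
        (1250.0, 0.0844),
        (1600.0, 0.0882),
        (2000.0, 0.0898),
        (2500.0, 0.0868),
        (3150.0, 0.0844),
        (4000.0, 0.0771),
        (5000.0, 0.0527),
        (6300.0, 0.0364),
        (8000.0, 0.0185),
    ]
)


def band_importance(center_frequencies: np.ndarray) -> np.ndarray:
    """SII-style importance weights at the given centers, summing to one."""
    centers = np.asarray(center_frequencies, dtype=float)
    table_f = _THIRD_OCTAVE_IMPORTANCE[:, 0]
    table_w = _THIRD_OCTAVE_IMPORTANCE[:, 1]
    weights = np.interp(
        np.log10(centers), np.log10(table_f), table_w, left=0.0, right=0.0
    )
    total = weights.sum()
    if total == 0:
        raise ValueError("no band center falls inside the importance table range")
    return weights / total


def uniform_importance(center_frequencies: np.ndarray) -> np.ndarray:
    """Equal weight per band (configuration switch)."""
    n = len(center_frequencies)
    return np.full(n, 1.0 / n)
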
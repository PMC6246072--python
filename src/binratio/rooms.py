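"""Synthetic binaural room impulse responses.

A shoebox image-source simulation with a parametric spherical-head receiver
produces the BRIRs the rest of the pipeline consumes.  The head contributes
a Woodworth ITD and a first-order high-shelf head-shadow ILD per incoming
direction; the room contributes image-source reflections whose uniform wall
reflectance is chosen from the configured reverberation time (T30) via the
Eyring relation.

Azimuth convention: 0° is frontal, positive azimuths are clockwise (to the
listener's right), range (-180, 180].  A positive ITD means the left ear
lags (source on the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signal import BinauralSignal, MonoSignal

SPEED_OF_SOUND = 343.0


@dataclass(frozen=True)
class HeadModel:
    """Parametric spherical-head receiver.

    radius : float
        Head radius in metres (default 8.75 cm).
    speed_of_sound : float
        In m/s.
    shadow_corner : float
        Corner frequency (Hz) of the contralateral high-shelf cut.
    shadow_depth_db : float
        Asymptotic high-frequency attenuation (dB) of the contralateral ear
        for a source at |azimuth| = 90°; scaled by sin|azimuth| otherwise.
    """

    radius: float = 0.0875
    speed_of_sound: float = SPEED_OF_SOUND
    shadow_corner: float = 1500.0
    shadow_depth_db: float = 15.0


def itd_woodworth(azimuth: float, head: HeadModel = HeadModel()) -> float:
    """Woodworth ITD in seconds for a source at the given azimuth (deg).

    ITD = (a/c) * (theta + sin(theta)) with theta the lateral angle folded
    front-back symmetrically; antisymmetric in azimuth, zero at 0° and 180°.
    """
    if not -180.0 < azimuth <= 180.0 + 1e-9:
        raise ValueError(f"azimuth {azimuth} outside (-180, 180]")
    lateral = abs(azimuth)
    if lateral > 90.0:
        lateral = 180.0 - lateral
    theta = np.deg2rad(lateral)
    itd = head.radius / head.speed_of_sound * (theta + np.sin(theta))
    return float(np.sign(azimuth) * itd) if abs(azimuth) != 180.0 else 0.0


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, acoustics and playback parameters of a synthetic scene."""

    room: tuple[float, float, float] = (6.0, 5.0, 3.0)
    t30: float = 0.2
    radius: float = 1.3
    azimuths: tuple[float, ...] = (0.0, 90.0, -90.0, 180.0)
    listener: tuple[float, float, float] = (3.0, 2.5, 1.5)
    aided: bool = False
    insertion_gain_db: float = 10.0
    playback_attenuation_db: float = 10.0
    rate: float = 44_100.0
    seed: int = 0
    head: HeadModel = field(default_factory=HeadModel)
    absorption: float | None = None  # None -> derived from t30 (Eyring); 1 -> anechoic
    brir_duration: float = 0.32

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("source ring radius must be positive")
        if self.t30 <= 0:
            raise ValueError("T30 must be positive")

    def wall_absorption(self) -> float:
        """Uniform wall absorption coefficient realizing the target T30.

        Sabine: T60 = 0.161 V / (alpha S).  For the shoebox image-source
        render, whose Schroeder decay is slightly slower than the
        mean-free-path argument suggests, the Sabine mapping reproduces the
        configured T30 more closely than Eyring's.
        """
        if self.absorption is not None:
            return self.absorption
        lx, ly, lz = self.room
        volume = lx * ly * lz
        surface = 2 * (lx * ly + lx * lz + ly * lz)
        alpha = 0.161 * volume / (surface * self.t30)
        if alpha >= 1.0:
            raise ValueError("room too small/dead for the requested T30")
        return float(alpha)


@dataclass(frozen=True)
class Brir:
    """Binaural room impulse response for one source position."""

    response: BinauralSignal
    azimuth: float
    distance: float
    aided: bool = False

    @property
    def rate(self) -> float:
        return self.response.rate

    def scaled(self, left: float, right: float) -> "Brir":
        return replace(
            self,
            response=BinauralSignal(
                self.response.left.scaled(left), self.response.right.scaled(right)
            ),
        )


def _source_position(cfg: SceneConfig, azimuth: float) -> np.ndarray:
    """Source on the ring: x to the listener's right, y frontal."""
    az = np.deg2rad(azimuth)
    lx, ly, lz = cfg.listener
    return np.array(
        [lx + cfg.radius * np.sin(az), ly + cfg.radius * np.cos(az), lz]
    )


def _shadow_sos(depth_db: float, corner: float, rate: float) -> np.ndarray:
    """First-order high-shelf cut (RBJ shelf), depth_db > 0 attenuates highs."""
    a_lin = 10.0 ** (-depth_db / 40.0)  # sqrt of the linear gain
    w0 = 2 * np.pi * corner / rate
    cosw, sinw = np.cos(w0), np.sin(w0)
    alpha = sinw / np.sqrt(2.0)
    ap1, am1 = a_lin + 1, a_lin - 1
    sq = 2 * np.sqrt(a_lin) * alpha
    b0 = a_lin * (ap1 + am1 * cosw + sq)
    b1 = -2 * a_lin * (am1 + ap1 * cosw)
    b2 = a_lin * (ap1 + am1 * cosw - sq)
    a0 = ap1 - am1 * cosw + sq
    a1 = 2 * (am1 - ap1 * cosw)
    a2 = ap1 - am1 * cosw - sq
    return np.array([[b0 / a0, b1 / a0, b2 / a0, 1.0, a1 / a0, a2 / a0]])


def _fractional_impulse(n_total: int, delay_samples: float, amplitude: float,
                        half_width: int = 40) -> tuple[np.ndarray, int]:
    """Windowed-sinc kernel realizing a fractional delay."""
    center = int(np.floor(delay_samples))
    frac = delay_samples - center
    k = np.arange(-half_width, half_width + 1)
    kernel = np.sinc(k - frac) * np.hanning(2 * half_width + 1)
    return amplitude * kernel, center - half_width


def _add_kernel(train: np.ndarray, kernel: np.ndarray, start: int) -> None:
    lo = max(start, 0)
    hi = min(start + len(kernel), len(train))
    if hi > lo:
        train[lo:hi] += kernel[lo - start : hi - start]


def _image_sources(cfg: SceneConfig, source: np.ndarray, max_dist: float):
    """Image-source positions, distances and reflection orders (vectorized)."""
    dims = np.asarray(cfg.room)
    listener = np.asarray(cfg.listener)
    grids = []
    for axis in range(3):
        n_max = int(np.ceil(max_dist / (2 * dims[axis]))) + 1
        grids.append(np.arange(-n_max, n_max + 1))
    positions, orders = [], []
    for p in range(8):
        parity = np.array([(p >> i) & 1 for i in range(3)])
        mirrored = np.where(parity == 1, -source, source)
        mx, my, mz = np.meshgrid(*grids, indexing="ij")
        shifts = np.stack([mx, my, mz], axis=-1).reshape(-1, 3) * 2 * dims
        pos = shifts + mirrored
        # wall hits per axis: |m - p| on the near wall + |m| on the far wall
        m = np.stack([mx, my, mz], axis=-1).reshape(-1, 3)
        order = np.abs(m - parity).sum(axis=1) + np.abs(m).sum(axis=1)
        positions.append(pos)
        orders.append(order)
    positions = np.concatenate(positions)
    orders = np.concatenate(orders)
    dist = np.linalg.norm(positions - listener, axis=1)
    keep = dist <= max_dist
    return positions[keep], dist[keep], orders[keep]


def simulate_brir(cfg: SceneConfig, azimuth: float) -> Brir:
    """Render the BRIR for one ring source by the image-source method.

    The direct path carries an exact (windowed-sinc) fractional delay with
    the Woodworth ITD split across the ears; reflections are rounded to the
    sample grid and jittered slightly (seeded) to avoid sweeping-echo
    artifacts.  Head shadow is applied per direction sector as a first-order
    high-shelf cut on the contralateral ear.
    """
    dims = np.asarray(cfg.room)
    listener = np.asarray(cfg.listener)
    if np.any(listener <= 0) or np.any(listener >= dims):
        raise ValueError("listener must be strictly inside the room")
    source = _source_position(cfg, azimuth)
    if np.any(source <= 0) or np.any(source >= dims):
        raise ValueError("source must be inside the room")

    rate = cfg.rate
    head = cfg.head
    c = head.speed_of_sound
    n_total = int(round(cfg.brir_duration * rate))
    alpha = cfg.wall_absorption()
    beta = np.sqrt(max(0.0, 1.0 - alpha))
    rng = np.random.default_rng([cfg.seed, int(round(azimuth)) % 360])

    n_sectors = 16
    sector_width = 360.0 / n_sectors
    trains = np.zeros((n_sectors, 2, n_total))

    def ear_delays(dist: float, az_img: float) -> tuple[float, float]:
        itd = itd_woodworth(az_img, head)
        base = dist / c * rate
        return base + itd / 2 * rate, base - itd / 2 * rate

    # direct path: exact fractional delay
    d0 = float(np.linalg.norm(source - listener))
    diff = source - listener
    az0 = float(np.rad2deg(np.arctan2(diff[0], diff[1])))
    sector0 = int(np.round(az0 / sector_width)) % n_sectors
    for ear, delay in enumerate(ear_delays(d0, az0)):
        kernel, start = _fractional_impulse(n_total, delay, 1.0 / d0)
        _add_kernel(trains[sector0, ear], kernel, start)

    if beta > 0.0:
        max_dist = cfg.brir_duration * c + 2.0
        positions, dist, orders = _image_sources(cfg, source, max_dist)
        direct = (orders == 0) & (np.abs(dist - d0) < 1e-9)
        positions, dist, orders = positions[~direct], dist[~direct], orders[~direct]
        # temporal jitter (±0.2 ms) decorrelates the sparse late reflections
        jitter = rng.uniform(-2e-4, 2e-4, size=len(dist)) * c
        dist = np.maximum(dist + jitter, 0.1)
        amps = beta**orders / dist
        rel = positions - listener
        az_img = np.rad2deg(np.arctan2(rel[:, 0], rel[:, 1]))
        itds = np.array([itd_woodworth(a, head) for a in np.round(az_img)])
        sectors = np.round(az_img / sector_width).astype(int) % n_sectors
        for ear, sign in ((0, +0.5), (1, -0.5)):
            idx = np.round((dist / c + sign * itds) * rate).astype(int)
            ok = (idx >= 0) & (idx < n_total)
            np.add.at(trains, (sectors[ok], ear, idx[ok]), amps[ok])

    # head shadow per sector: contralateral high-shelf cut
    out = np.zeros((2, n_total))
    for s in range(n_sectors):
        az_s = s * sector_width
        if az_s > 180.0:
            az_s -= 360.0
        lateral = np.sin(np.deg2rad(abs(az_s if abs(az_s) <= 90 else 180 - abs(az_s))))
        depth = head.shadow_depth_db * lateral
        contra = 0 if az_s > 0 else 1  # left ear shadowed for right-side sources
        for ear in range(2):
            band = trains[s, ear]
            if not band.any():
                continue
            if depth > 1e-6 and ear == contra and az_s != 0.0:
                sos = _shadow_sos(depth, head.shadow_corner, rate)
                out[ear] += sps.sosfilt(sos, band)
            else:
                out[ear] += band
    return Brir(
        response=BinauralSignal.from_arrays(out[0], out[1], rate),
        azimuth=azimuth,
        distance=d0,
        aided=False,
    )


def schroeder_t30(ir: MonoSignal, fit_range: tuple[float, float] = (-5.0, -35.0)) -> float:
    """Reverberation time from backward-integrated energy decay.

    Fits a line to the Schroeder curve between ``fit_range`` dB (default −5
    to −35) and extrapolates to −60 dB.
    """
    energy = np.cumsum(ir.samples[::-1] ** 2)[::-1]
    energy = energy / energy[0]
    with np.errstate(divide="ignore"):
        decay_db = 10.0 * np.log10(energy)
    t = np.arange(len(decay_db)) / ir.rate
    hi, lo = fit_range
    mask = (decay_db <= hi) & (decay_db >= lo) & np.isfinite(decay_db)
    if mask.sum() < 10:
        raise ValueError("decay range too short for a T30 fit")
    slope, _ = np.polyfit(t[mask], decay_db[mask], 1)
    return float(-60.0 / slope)
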
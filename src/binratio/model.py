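"""Short-term binaural speech-intelligibility model.

The model predicts the energetic-masking component of binaural speech
intelligibility from two ear-signal pairs: the target alone and the sum of
all interferers.  Per gammatone band it combines

* better-ear listening — the larger of the two ears' target-to-interferer
  ratios, capped by a ceiling (20 dB) so interferer pauses cannot drive the
  ratio to infinity, and

* binaural unmasking — an equalization–cancellation (EC) advantage

  ``BU = 10 log10[(k - cos(phi_T - phi_I)) / (k - rho)]``

  with ``k = (1 + sigma_eps^2) * exp(omega^2 * sigma_del^2)``, where
  ``phi_T``/``phi_I`` are the target/interferer interaural phases, ``rho``
  is the interferer interaural coherence and the sigmas are the internal
  amplitude/time jitters limiting cancellation.

Target statistics are long-term (computed once per condition) while the
interferer is analysed in 24-ms half-overlapping frames, so target speech
pauses cannot masquerade as unintelligibility while interferer dips are
still exploited (dip listening).  Band values are combined with
band-importance weights and the per-frame broadband ratios averaged (in dB)
into the scalar "binaural ratio"; differences of binaural ratios between
conditions predict SRT differences with inverted sign, no fitting involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .framing import FrameGrid
from .gammatone import GammatoneBank, design_gammatone_bank
from .signal import BinauralSignal, MonoSignal
from .sii import band_importance, uniform_importance
from .stats import LONG_TERM, FrameStats, interaural_stats

NEG_INF_DB = -np.inf


@dataclass(frozen=True)
class EcParameters:
    """Internal-noise constants of the equalization–cancellation stage.

    sigma_epsilon : float
        Amplitude-jitter coefficient (default 0.25).
    sigma_delta : float
        Time jitter in seconds (default 105 µs).
    floor_at_zero : bool
        Clamp the unmasking advantage at 0 dB (cancellation cannot hurt).
    """

    sigma_epsilon: float = 0.25
    sigma_delta: float = 105e-6
    floor_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.sigma_epsilon < 0 or self.sigma_delta < 0:
            raise ValueError("EC jitter parameters must be non-negative")


@dataclass(frozen=True)
class ModelConfig:
    """Everything the model needs besides the two ear-signal pairs."""

    ceiling_db: float = 20.0
    grid: FrameGrid = field(default_factory=FrameGrid)
    bank: GammatoneBank = field(default_factory=design_gammatone_bank)
    ec: EcParameters = field(default_factory=EcParameters)
    weighting: str = "sii"  # "sii" | "uniform"
    masker_duration: float = 120.0

    def weights(self) -> np.ndarray:
        if self.weighting == "sii":
            return band_importance(self.bank.center_frequencies)
        if self.weighting == "uniform":
            return uniform_importance(self.bank.center_frequencies)
        raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class TargetStats:
    """Long-term target statistics: per-band ear powers and interaural phase."""

    center_frequencies: np.ndarray
    power_left: np.ndarray  # (n_bands,)
    power_right: np.ndarray
    phase: np.ndarray


@dataclass(frozen=True)
class ModelOutput:
    """Model components and the scalar binaural ratio (all in dB)."""

    center_frequencies: np.ndarray
    better_ear_db: np.ndarray  # (n_bands, n_frames)
    binaural_unmasking_db: np.ndarray  # (n_bands, n_frames)
    frame_ratio_db: np.ndarray  # (n_frames,)
    binaural_ratio_db: float
    weights: np.ndarray

    @property
    def better_ear_component_db(self) -> float:
        """Frame-averaged, band-weighted better-ear part of the ratio."""
        return float(np.mean(self.weights @ self.better_ear_db))

    @property
    def binaural_unmasking_component_db(self) -> float:
        """Frame-averaged, band-weighted unmasking part of the ratio."""
        return float(np.mean(self.weights @ self.binaural_unmasking_db))


def average_target(
    sentences: list[MonoSignal],
    collocated_masker_rms: float,
    skip: float = 0.680,
) -> MonoSignal:
    """Average a sentence set into the model's target representative.

    Each sentence is trimmed by ``skip`` seconds at the start, all are
    truncated to the shortest remaining length, averaged sample-wise, and
    the result's RMS is equalized to the collocated masker's RMS.
    """
    if len(sentences) < 2:
        raise ValueError("need at least two sentences to average")
    rate = sentences[0].rate
    skip_n = int(round(skip * rate))
    trimmed = []
    for s in sentences:
        if s.rate != rate:
            raise ValueError("sentences must share one sampling rate")
        if len(s) <= skip_n:
            raise ValueError("sentence shorter than the skip interval")
        trimmed.append(s.samples[skip_n:])
    n = min(len(t) for t in trimmed)
    mean = np.mean([t[:n] for t in trimmed], axis=0)
    return MonoSignal(mean, rate).with_rms(collocated_masker_rms)


def target_stats(target_ears: BinauralSignal, bank: GammatoneBank) -> TargetStats:
    """Long-term per-band target powers and interaural phase (computed once)."""
    if target_ears.left.rms() == 0 and target_ears.right.rms() == 0:
        raise ValueError("target ear signals are silent")
    stats = interaural_stats(target_ears, bank, LONG_TERM)
    return TargetStats(
        center_frequencies=bank.center_frequencies,
        power_left=stats.power_left[:, 0],
        power_right=stats.power_right[:, 0],
        phase=stats.phase[:, 0],
    )


def better_ear(ts: TargetStats, fs: FrameStats, ceiling_db: float = 20.0) -> np.ndarray:
    """Better-ear target-to-interferer ratio per band and frame, in dB.

    The larger of the two ears' ratios, capped at ``ceiling_db``.  Where the
    interferer is silent at both ears the ratio is the ceiling; where the
    target has no power the ratio is −inf (propagates as a very poor band).
    """
    if len(ts.center_frequencies) != fs.n_bands:
        raise ValueError("target and interferer statistics use different banks")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_l = ts.power_left[:, None] / fs.power_left
        ratio_r = ts.power_right[:, None] / fs.power_right
        best = np.fmax(ratio_l, ratio_r)  # fmax ignores NaN from 0/0
        be = 10.0 * np.log10(best)
    silent_interferer = (fs.power_left == 0) & (fs.power_right == 0)
    be[silent_interferer] = ceiling_db
    silent_target = (ts.power_left == 0) & (ts.power_right == 0)
    be[silent_target, :] = NEG_INF_DB
    return np.minimum(be, ceiling_db)


def bmld_factor(center_frequencies: np.ndarray, ec: EcParameters) -> np.ndarray:
    """EC internal-noise factor k(f) = (1 + sigma_eps^2) exp(omega^2 sigma_del^2)."""
    omega = 2.0 * np.pi * np.asarray(center_frequencies)
    return (1.0 + ec.sigma_epsilon**2) * np.exp((omega * ec.sigma_delta) ** 2)


def binaural_unmasking(
    ts: TargetStats, fs: FrameStats, ec: EcParameters = EcParameters()
) -> np.ndarray:
    """EC binaural-unmasking advantage per band and frame, in dB.

    ``BU = 10 log10[(k - cos(phi_T - phi_I)) / (k - rho)]`` — zero whenever
    the interferer power vanishes at either ear in a band/frame, and floored
    at 0 dB when configured.
    """
    if len(ts.center_frequencies) != fs.n_bands:
        raise ValueError("target and interferer statistics use different banks")
    rho = fs.coherence
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("interferer coherence outside [0, 1]")
    k = bmld_factor(ts.center_frequencies, ec)[:, None]
    phase_diff = ts.phase[:, None] - fs.phase
    bu = 10.0 * np.log10((k - np.cos(phase_diff)) / (k - rho))
    silent_either_ear = (fs.power_left == 0) | (fs.power_right == 0)
    bu[silent_either_ear] = 0.0
    if ec.floor_at_zero:
        bu = np.maximum(bu, 0.0)
    return bu


def integrate(
    be: np.ndarray, bu: np.ndarray, cfg: ModelConfig
) -> ModelOutput:
    """Band-weight and frame-average BE + BU into the binaural ratio."""
    weights = cfg.weights()
    if be.shape != bu.shape or be.shape[0] != len(weights):
        raise ValueError("component shapes do not match the configured bank")
    effective = be + bu
    frame_ratio = weights @ effective
    return ModelOutput(
        center_frequencies=cfg.bank.center_frequencies,
        better_ear_db=be,
        binaural_unmasking_db=bu,
        frame_ratio_db=frame_ratio,
        binaural_ratio_db=float(np.mean(frame_ratio)),
        weights=weights,
    )


def predict_condition(
    target_ears: BinauralSignal,
    interferer_ears: BinauralSignal,
    cfg: ModelConfig = ModelConfig(),
    short_term: bool = True,
) -> ModelOutput:
    """End-to-end prediction for one condition.

    Target statistics are computed once over the whole target rendering;
    interferer statistics per 24-ms frame (or once, for the long-term model
    variant with ``short_term=False``).  At most ``cfg.masker_duration``
    seconds of the interferer signal are analysed.
    """
    n_max = int(round(cfg.masker_duration * interferer_ears.rate))
    if len(interferer_ears) > n_max:
        interferer_ears = BinauralSignal.from_arrays(
            interferer_ears.left.samples[:n_max],
            interferer_ears.right.samples[:n_max],
            interferer_ears.rate,
        )
    ts = target_stats(target_ears, cfg.bank)
    grid = cfg.grid if short_term else LONG_TERM
    fs = interaural_stats(interferer_ears, cfg.bank, grid)
    be = better_ear(ts, fs, cfg.ceiling_db)
    bu = binaural_unmasking(ts, fs, cfg.ec)
    return integrate(be, bu, cfg)


def long_term_model(
    target_ears: BinauralSignal,
    interferer_ears: BinauralSignal,
    cfg: ModelConfig = ModelConfig(),
) -> ModelOutput:
    """Model variant using one whole-signal frame instead of 24-ms frames."""
    return predict_condition(target_ears, interferer_ears, cfg, short_term=False)


def ha_disadvantage(aided: ModelOutput, unaided: ModelOutput) -> float:
    """Predicted SRT increase (dB) caused by the hearing aids.

    Binaural ratios are inversely related to SRTs, so the disadvantage is
    the unaided minus the aided binaural ratio.
    """
    return unaided.binaural_ratio_db - aided.binaural_ratio_db


def predicted_srm(separated: ModelOutput, collocated: ModelOutput) -> float:
    """Predicted spatial release from masking (dB): separated − collocated."""
    return separated.binaural_ratio_db - collocated.binaural_ratio_db
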
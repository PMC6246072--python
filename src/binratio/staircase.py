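"""Adaptive 1-up-1-down SRT measurement with simulated listeners.

A synthetic listener answers Bernoulli trials along a logistic psychometric
function; the staircase lowers the target level after a correct response and
raises it after an error, converging on the 50% point (the speech reception
threshold, SRT).  A run comprises 16–32 trials: from trial 16 on it stops as
soon as the standard error of the threshold estimate drops below 0.8 dB.

The threshold estimator is a fixed-slope logistic maximum-likelihood fit to
all (level, response) pairs; its standard error comes from the observed
Fisher information.  A reversal-midpoint average is kept as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass(frozen=True)
class PsychometricListener:
    """Logistic synthetic listener.

    true_srt : float
        Level (dB) at which half the responses are correct (lapse-free).
    slope : float
        Psychometric slope in probability per dB at the midpoint.
    lapse : float
        Lapse rate in [0, 0.1]; scales the upper asymptote to 1 − lapse.
    """

    true_srt: float
    slope: float = 0.15
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def p_correct(self, level: float | np.ndarray) -> float | np.ndarray:
        """Probability of a correct response at the given level (dB)."""
        k = 4.0 * self.slope  # logistic rate giving `slope` prob/dB at midpoint
        return (1.0 - self.lapse) / (1.0 + np.exp(-k * (np.asarray(level) - self.true_srt)))


def respond(
    listener: PsychometricListener,
    level: float,
    rng: int | np.random.Generator,
) -> bool:
    """One Bernoulli trial of the listener at the given level."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return bool(rng.random() < listener.p_correct(level))


@dataclass(frozen=True)
class AdaptiveTrack:
    """Record of one adaptive run and its threshold estimate."""

    levels: np.ndarray  # presented level per trial (dB)
    responses: np.ndarray  # correct flag per trial
    estimate: float  # SRT (dB)
    standard_error: float  # dB
    reversal_estimate: float  # cross-check: mean of reversal midpoints

    @property
    def n_trials(self) -> int:
        return len(self.levels)

    def to_frame(self):
        """Trial log: one row per trial (level, response)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "level_db": self.levels,
                "correct": self.responses,
            }
        )


def fit_threshold(
    levels: np.ndarray, responses: np.ndarray, slope: float
) -> tuple[float, float]:
    """Fixed-slope logistic ML threshold and its standard error.

    The slope is held at the assumed listener slope (prob/dB at midpoint);
    only the threshold is free.  SE = 1/sqrt(information), with the logistic
    observed information  sum k^2 p (1-p).
    """
    levels = np.asarray(levels, float)
    responses = np.asarray(responses, bool)
    k = 4.0 * slope

    def nll(theta: float) -> float:
        z = k * (levels - theta)
        # log(1+e^-z) computed stably
        log_p = -np.logaddexp(0.0, -z)
        log_q = -np.logaddexp(0.0, z)
        return -float(np.sum(np.where(responses, log_p, log_q)))

    span = levels.max() - levels.min() + 20.0
    res = minimize_scalar(
        nll, bounds=(levels.min() - span, levels.max() + span), method="bounded"
    )
    theta = float(res.x)
    p = 1.0 / (1.0 + np.exp(-k * (levels - theta)))
    information = float(np.sum(k * k * p * (1.0 - p)))
    se = 1.0 / np.sqrt(information) if information > 0 else np.inf
    return theta, se


def _reversal_midpoints(levels: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Levels midway between consecutive direction reversals."""
    directions = np.where(responses, -1, 1)  # next step direction
    reversals = np.flatnonzero(directions[1:] != directions[:-1]) + 1
    if len(reversals) < 2:
        return np.array([])
    rev_levels = levels[reversals]
    return (rev_levels[1:] + rev_levels[:-1]) / 2.0


def run_track(
    listener: PsychometricListener,
    start_level: float,
    step: float = 2.0,
    seed: int | np.random.Generator = 0,
    min_trials: int = 16,
    max_trials: int = 32,
    se_target: float = 0.8,
    assumed_slope: float | None = None,
) -> AdaptiveTrack:
    """Run one 1-up-1-down adaptive track.

    The level decreases by ``step`` after a correct response and increases
    after an incorrect one.  The run ends at the first trial >=
    ``min_trials`` where the threshold standard error falls below
    ``se_target`` (0.8 dB), or at ``max_trials``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    slope = listener.slope if assumed_slope is None else assumed_slope
    levels: list[float] = []
    responses: list[bool] = []
    level = start_level
    estimate, se = np.nan, np.inf
    while True:
        correct = respond(listener, level, rng)
        levels.append(level)
        responses.append(correct)
        level = level - step if correct else level + step
        n = len(levels)
        if n >= min_trials:
            estimate, se = fit_threshold(np.array(levels), np.array(responses), slope)
            if se < se_target or n >= max_trials:
                break
    mids = _reversal_midpoints(np.array(levels), np.array(responses))
    reversal_estimate = float(np.mean(mids)) if len(mids) else estimate
    return AdaptiveTrack(
        levels=np.array(levels),
        responses=np.array(responses),
        estimate=estimate,
        standard_error=se,
        reversal_estimate=reversal_estimate,
    )


def srm(separated_srt: float, collocated_srt: float) -> float:
    """Spatial release from masking: collocated − separated SRT (dB)."""
    return collocated_srt - separated_srt


def ha_disadvantage_measured(aided_srt: float, unaided_srt: float) -> float:
    """Measured hearing-aid disadvantage: aided − unaided SRT (dB)."""
    return aided_srt - unaided_srt
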
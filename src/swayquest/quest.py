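"""Grid-based Bayesian adaptive threshold estimation (QUEST).

The engine maintains a discrete posterior over candidate detection
thresholds of a Weibull psychometric observer.  After every trial the
posterior is updated with the Bernoulli likelihood of the observed
response and the next probe intensity is placed at the posterior mean,
quantized to the integer device units the stimulation hardware accepts.

Two psychometric parameterizations are supported:

``log10``
    The classic Weibull in log10 intensity,
    ``p(x) = delta*gamma + (1-delta)*(1 - (1-gamma)*exp(-10**(beta*(x-t))))``
    with ``x = log10(I)`` and ``t = log10(T)``, which is algebraically the
    ratio form ``exp(-(I/T)**beta)`` in linear device units.  This is the
    default: the beta = 3.5 convention for adaptive tactile psychophysics
    belongs to this form.

``linear``
    The same expression evaluated with ``x`` and ``t`` taken directly in
    device units (a shifted, Gumbel-type sigmoid), for devices whose unit
    steps are perceptually linear.

Both forms share the asymptotes: guess rate ``gamma`` at zero intensity
and ``1 - delta*(1-gamma)`` at high intensity, and both place the
threshold ``T`` at the intensity where the delta- and gamma-free core
reaches ``1 - 1/e``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PsychometricModel",
    "QuestPosterior",
    "StimulusIntensity",
    "init_posterior",
    "p_detect",
    "update_posterior",
    "recommend_intensity",
    "round_half_away",
]

# Log-probabilities are clipped here so a long run of one response can
# never zero out the whole grid in double precision.
_LOG_P_FLOOR = -745.0


@dataclass(frozen=True)
class PsychometricModel:
    """Weibull yes/no observer model.

    Parameters
    ----------
    beta:
        Slope of the psychometric function (dimensionless, > 0).
    gamma:
        Guess rate: probability of a "detected" report at zero intensity.
    delta:
        Lapse rate: probability of an attention lapse on any trial.
    intensity_scale:
        ``"log10"`` (ratio Weibull, default) or ``"linear"`` (shifted form).
    """

    beta: float = 3.5
    gamma: float = 0.01
    delta: float = 0.01
    intensity_scale: str = "log10"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if self.intensity_scale not in ("log10", "linear"):
            raise ValueError(
                f"intensity_scale must be 'log10' or 'linear', got {self.intensity_scale!r}"
            )


@dataclass(frozen=True)
class StimulusIntensity:
    """A raw posterior-mean recommendation and its integer device command."""

    raw: float
    quantized: int


@dataclass
class QuestPosterior:
    """Discrete posterior over candidate detection thresholds.

    ``log_weights`` are kept unnormalized internally; ``normalize`` brings
    them to a proper log probability mass function.  All updates run in
    log space so that long response runs cannot underflow the grid.
    """

    threshold_grid: np.ndarray
    log_weights: np.ndarray
    prior_mean: float
    prior_sd: float
    model: PsychometricModel
    intensity_range: tuple[int, int] = (1, 100)
    n_updates: int = 0

    def normalize(self) -> None:
        self.log_weights = self.log_weights - logsumexp(self.log_weights)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights - logsumexp(self.log_weights))

    @property
    def mean(self) -> float:
        return float(np.sum(self.weights * self.threshold_grid))

    @property
    def sd(self) -> float:
        w = self.weights
        m = np.sum(w * self.threshold_grid)
        return float(np.sqrt(np.sum(w * (self.threshold_grid - m) ** 2)))


def init_posterior(
    prior_mean: float,
    prior_sd: float,
    model: PsychometricModel | None = None,
    *,
    n_points: int = 201,
    span_sd: float = 5.0,
    intensity_range: tuple[int, int] = (1, 100),
) -> QuestPosterior:
    """Build a Gaussian-prior posterior on a uniform threshold grid.

    The grid spans ``prior_mean ± span_sd * prior_sd`` (clipped below at a
    small positive value so thresholds stay physical) with ``n_points``
    uniformly spaced candidates in the model's intensity scale.
    """
    model = model or PsychometricModel()
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be > 0, got {prior_sd}")
    if n_points < 2:
        raise ValueError(f"grid needs at least 2 points, got {n_points}")
    lo = prior_mean - span_sd * prior_sd
    hi = prior_mean + span_sd * prior_sd
    if model.intensity_scale == "log10":
        # thresholds must stay positive for the ratio form
        lo = max(lo, 1e-3)
    if hi <= lo:
        raise ValueError("degenerate grid: upper edge not above lower edge")
    grid = np.linspace(lo, hi, n_points)
    log_w = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    post = QuestPosterior(
        threshold_grid=grid,
        log_weights=log_w,
        prior_mean=float(prior_mean),
        prior_sd=float(prior_sd),
        model=model,
        intensity_range=intensity_range,
    )
    post.normalize()
    return post


def p_detect(
    intensity: float | np.ndarray,
    threshold: float | np.ndarray,
    model: PsychometricModel,
) -> float | np.ndarray:
    """Detection probability of a Weibull observer.

    Non-decreasing in ``intensity``, non-increasing in ``threshold``;
    lower asymptote ``gamma``, upper asymptote ``1 - delta*(1-gamma)``.
    """
    intensity = np.asarray(intensity, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if model.intensity_scale == "log10":
        with np.errstate(divide="ignore"):
            core = 1.0 - np.exp(
                -np.power(np.maximum(intensity, 0.0) / threshold, model.beta)
            )
    else:
        core = 1.0 - np.exp(-np.power(10.0, model.beta * (intensity - threshold)))
    p = model.delta * model.gamma + (1.0 - model.delta) * (
        model.gamma + (1.0 - model.gamma) * core
    )
    if p.ndim == 0:
        return float(p)
    return p


def update_posterior(
    posterior: QuestPosterior, intensity: int, response: bool
) -> QuestPosterior:
    """Bayes-update the posterior with one trial's response.

    Each candidate's weight is multiplied by ``p_detect`` (detected) or
    ``1 - p_detect`` (not detected); the product is accumulated in log
    space and renormalized.  Returns a new posterior; the input is left
    untouched.
    """
    p = np.asarray(
        p_detect(float(intensity), posterior.threshold_grid, posterior.model)
    )
    like = p if response else 1.0 - p
    with np.errstate(divide="ignore"):
        log_like = np.maximum(np.log(like), _LOG_P_FLOOR)
    new_log_w = posterior.log_weights + log_like
    if not np.isfinite(logsumexp(new_log_w)):
        raise ValueError("posterior vanished after update: model/grid inconsistent")
    out = replace(posterior, log_weights=new_log_w, n_updates=posterior.n_updates + 1)
    out.normalize()
    return out


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def recommend_intensity(posterior: QuestPosterior) -> StimulusIntensity:
    """Place the next probe at the posterior mean, quantized to device units.

    The integer command is clipped to the device's admissible range
    (never below 1: a zero-amplitude stimulus is undefined).
    """
    raw = posterior.mean
    lo, hi = posterior.intensity_range
    q = min(max(round_half_away(raw), lo), hi)
    return StimulusIntensity(raw=raw, quantized=q)
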
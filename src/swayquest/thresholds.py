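"""Detection-threshold determination from adaptive-track block logs.

A block's threshold is not a fitted psychometric parameter but the
plateau of the integer-quantized QUEST recommendations: the first trial
after which the recommended probe intensity never changes again.  A
converged threshold is only *valid* if the observer kept producing both
"detected" and "not detected" reports in the trials after convergence —
the natural behavior at an intensity near one's true threshold.  Blocks
failing that check are excluded together with their kinematic data.

Δthresholds subtract a baseline threshold (quiet standing, or sitting)
from each perturbation-interval threshold, so positive values mean
poorer tactile sensitivity than baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TrialRecord",
    "ThresholdEstimate",
    "DeltaThreshold",
    "find_convergence",
    "validate_threshold",
    "estimate_block_threshold",
    "delta_thresholds",
]

INTERVALS = ("early", "late", "after")


@dataclass(frozen=True)
class TrialRecord:
    """One psychophysics trial of an adaptive track."""

    trial_index: int              # 1-based within its track
    block_id: str
    condition: str
    interval_label: str           # early | late | after | single
    presented_intensity: int
    response: int                 # 1 detected, 0 not detected
    raw_recommendation: float     # posterior mean after this trial's update
    quantized_recommendation: int


@dataclass(frozen=True)
class ThresholdEstimate:
    """A block's converged threshold with its validity flag."""

    value: int | None
    convergence_trial: int | None
    valid: bool
    n_trials_to_estimate: int | None
    block_id: str = ""
    condition: str = ""
    interval_label: str = ""


@dataclass(frozen=True)
class DeltaThreshold:
    condition: str
    interval_label: str
    delta: float | None           # None when either operand was invalid


def find_convergence(recommendations: Sequence[int]) -> int | None:
    """First index (1-based) after which the recommendation never changes.

    Returns ``None`` when the final two entries differ (the track never
    reached a plateau that survives to the end of the block).
    """
    recs = list(recommendations)
    if not recs:
        raise ValueError("empty recommendation sequence")
    if len(recs) >= 2 and recs[-1] != recs[-2]:
        return None
    k = len(recs)
    while k > 1 and recs[k - 2] == recs[-1]:
        k -= 1
    return k


def validate_threshold(responses_after_convergence: Sequence[int]) -> bool:
    """Valid iff both response categories occur after convergence.

    An empty remainder (convergence on the final trial) can never show
    both categories and is therefore invalid.
    """
    seen = set(int(r) for r in responses_after_convergence)
    return 0 in seen and 1 in seen


def estimate_block_threshold(trials: Sequence[TrialRecord]) -> ThresholdEstimate:
    """Threshold of one adaptive track (30 trials of one interval label).

    Applies the plateau rule to the post-trial quantized recommendations
    and the validity rule to the responses of the remaining trials.
    """
    if not trials:
        raise ValueError("empty block log")
    labels = {t.interval_label for t in trials}
    if len(labels) > 1:
        raise ValueError(f"block log mixes interval labels: {sorted(labels)}")
    ordered = sorted(trials, key=lambda t: t.trial_index)
    recs = [t.quantized_recommendation for t in ordered]
    k = find_convergence(recs)
    meta = dict(
        block_id=ordered[0].block_id,
        condition=ordered[0].condition,
        interval_label=ordered[0].interval_label,
    )
    if k is None:
        return ThresholdEstimate(
            value=None, convergence_trial=None, valid=False,
            n_trials_to_estimate=None, **meta,
        )
    remaining = [t.response for t in ordered[k:]]
    return ThresholdEstimate(
        value=int(recs[k - 1]),
        convergence_trial=k,
        valid=validate_threshold(remaining),
        n_trials_to_estimate=k,
        **meta,
    )


def delta_thresholds(
    perturbation_estimates: Sequence[ThresholdEstimate],
    baseline_estimate: ThresholdEstimate,
) -> list[DeltaThreshold]:
    """Baseline-normalize one perturbation block's interval thresholds.

    ``delta = interval threshold - baseline threshold``.  An invalid
    baseline voids all three deltas of the block (normalization is
    impossible); an invalid interval estimate voids only its own delta.
    """
    out: list[DeltaThreshold] = []
    base_ok = baseline_estimate.valid and baseline_estimate.value is not None
    for est in perturbation_estimates:
        if base_ok and est.valid and est.value is not None:
            d: float | None = float(est.value - baseline_estimate.value)
        else:
            d = None
        out.append(DeltaThreshold(est.condition, est.interval_label, d))
    return out


def trials_to_estimate(estimates: Sequence[ThresholdEstimate]) -> np.ndarray:
    """Trials-to-threshold counts over the valid estimates."""
    return np.array(
        [e.n_trials_to_estimate for e in estimates if e.valid], dtype=float
    )
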
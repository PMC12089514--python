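"""Cleaning and sway metrics for anterior–posterior COP/head traces.

Sign convention: anterior displacement is negative, posterior positive,
so a backward lean in reaction to an approaching visual scene shows up
as a positive excursion.  COP is sampled at 300 Hz from a force plate,
head position at 90 Hz from a headset; each stream is processed at its
native rate.

The per-trial pipeline runs in a fixed order:

1. drop trials with >= 100 ms of continuously missing samples,
2. re-reference each trace to its first 0.5 s of quiet stance,
3. blank samples displaced more than 15 cm (set to missing, never
   interpolated),
4. smooth with a 100 ms symmetric moving average (missing samples are
   skipped; the window shrinks at trial edges),
5. compute the anticipatory metric (max |displacement| in the 2.25 s
   before perturbation onset) and the reactive amplitude (post-onset
   positive maximum minus the preceding minimum, within 3.5 s of onset).

Condition-averaged metrics are normalized by subtracting the same metric
from quiet-stance baseline trials, so values above zero mean more sway
than baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "KinematicTrace",
    "SwayMetrics",
    "exclude_gapped_trials",
    "normalize_to_quiet_stance",
    "remove_outlier_samples",
    "smooth_moving_average",
    "anticipatory_metric",
    "reactive_metric",
    "normalize_metric_to_baseline",
    "filter_trials_to_threshold_set",
    "clean_trace",
]

GAP_THRESHOLD_S = 0.100        # continuous-missing run that drops a trial
OUTLIER_DISPLACEMENT_M = 0.15  # |displacement| above this is blanked
SMOOTH_WINDOW_S = 0.100
QUIET_STANCE_REF_S = 0.5
ANTICIPATORY_WINDOW_S = 2.25
REACTIVE_WINDOW_S = 3.5
TRIAL_DURATION_S = 7.0


@dataclass
class KinematicTrace:
    """Uniformly sampled anterior–posterior position series for one trial.

    Missing samples are NaN in ``samples``; ``onset`` is the trial's
    perturbation onset in seconds from trial start.
    """

    samples: np.ndarray          # metres; NaN = missing
    rate: float                  # Hz (300 for COP, 90 for head)
    onset: float                 # s
    stream: str = "cop"          # "cop" | "head"

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def copy_with(self, samples: np.ndarray) -> "KinematicTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class SwayMetrics:
    anticipatory: float | None       # metres, >= 0 (None when window missing)
    reactive_amplitude: float | None  # metres, >= 0


def _longest_missing_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    edges = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def exclude_gapped_trials(trace: KinematicTrace, gap_s: float = GAP_THRESHOLD_S) -> bool:
    """True (keep) unless any continuous missing run spans >= ``gap_s``."""
    mask = np.isnan(trace.samples)
    limit = int(round(gap_s * trace.rate))
    return _longest_missing_run(mask) < limit


def normalize_to_quiet_stance(trace: KinematicTrace) -> KinematicTrace:
    """Subtract the mean of the first 0.5 s (quiet stance) from every sample."""
    n_ref = int(round(QUIET_STANCE_REF_S * trace.rate))
    ref = trace.samples[:n_ref]
    if np.all(np.isnan(ref)):
        raise ValueError("quiet-stance reference window is fully missing")
    return trace.copy_with(trace.samples - np.nanmean(ref))


def remove_outlier_samples(
    trace: KinematicTrace, limit_m: float = OUTLIER_DISPLACEMENT_M
) -> KinematicTrace:
    """Blank samples whose |displacement| exceeds the limit (strict)."""
    x = trace.samples.copy()
    x[np.abs(x) > limit_m] = np.nan
    return trace.copy_with(x)


def smoothing_window_samples(rate: float, window_s: float = SMOOTH_WINDOW_S) -> int:
    """Odd window length closest to 100 ms at this rate (31 @ 300 Hz, 9 @ 90 Hz)."""
    n = int(round(window_s * rate))
    return n + 1 if n % 2 == 0 else n


def smooth_moving_average(
    trace: KinematicTrace, window_s: float = SMOOTH_WINDOW_S
) -> KinematicTrace:
    """Centered moving average over ~100 ms.

    Missing samples are excluded from each window's mean and stay missing
    in the output; at the trial edges the window shrinks rather than pad.
    """
    w = smoothing_window_samples(trace.rate, window_s)
    sm = (
        pd.Series(trace.samples)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    sm[np.isnan(trace.samples)] = np.nan
    return trace.copy_with(sm)


def clean_trace(
    trace: KinematicTrace,
    gap_s: float = GAP_THRESHOLD_S,
    limit_m: float = OUTLIER_DISPLACEMENT_M,
    window_s: float = SMOOTH_WINDOW_S,
) -> KinematicTrace | None:
    """Full cleaning chain; None when the trial must be dropped."""
    if not exclude_gapped_trials(trace, gap_s):
        return None
    out = normalize_to_quiet_stance(trace)
    out = remove_outlier_samples(out, limit_m)
    return smooth_moving_average(out, window_s)


def _window_indices(trace: KinematicTrace, t0: float, t1: float,
                    include_end: bool) -> np.ndarray:
    t = trace.times
    if include_end:
        return np.flatnonzero((t >= t0) & (t <= t1))
    return np.flatnonzero((t >= t0) & (t < t1))


def anticipatory_metric(
    trace: KinematicTrace,
    onset: float | None = None,
    window_s: float = ANTICIPATORY_WINDOW_S,
) -> float | None:
    """Max |displacement| in the 2.25 s before perturbation onset.

    The sample at onset itself is excluded (the window is half-open);
    missing samples are ignored.  None when the window is fully missing.
    """
    onset = trace.onset if onset is None else onset
    idx = _window_indices(trace, onset - window_s, onset, include_end=False)
    x = trace.samples[idx]
    if x.size == 0 or np.all(np.isnan(x)):
        return None
    return float(np.nanmax(np.abs(x)))


def reactive_metric(
    trace: KinematicTrace,
    onset: float | None = None,
    window_s: float = REACTIVE_WINDOW_S,
) -> float | None:
    """Posterior reactive amplitude within 3.5 s of perturbation onset.

    The positive (posterior) maximum after onset, minus the minimum that
    occurred between onset and that maximum.  Always >= 0.
    """
    onset = trace.onset if onset is None else onset
    idx = _window_indices(trace, onset, onset + window_s, include_end=True)
    x = trace.samples[idx]
    if x.size == 0 or np.all(np.isnan(x)):
        return None
    i_max = int(np.nanargmax(x))
    return float(x[i_max] - np.nanmin(x[: i_max + 1]))


def normalize_metric_to_baseline(
    perturbation_metric: float | None, baseline_metric: float | None
) -> float | None:
    """Perturbation metric minus its quiet-stance baseline counterpart."""
    if perturbation_metric is None or baseline_metric is None:
        return None
    return perturbation_metric - baseline_metric


def filter_trials_to_threshold_set(
    trial_indices: np.ndarray, convergence_trial: int | None
) -> np.ndarray:
    """Keep only trials that contributed to the threshold estimate.

    Kinematic analysis uses the trials up to and including the track's
    convergence trial; an invalid block (``convergence_trial=None``)
    keeps nothing.
    """
    trial_indices = np.asarray(trial_indices)
    if convergence_trial is None:
        return np.zeros(len(trial_indices), dtype=bool)
    return trial_indices <= convergence_trial
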
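"""Synthetic experiments: schedules, observers, responses, sway traces.

Emulates the moving-room balance study end to end so every analysis
stage runs without any recorded data:

* **Schedules** follow the study design: 7 s trials; a 30-trial training
  block; two 90-trial perturbation blocks (low temporal uncertainty:
  onset exactly 3 s after a countdown; high: onset uniform in 2.25–3 s,
  no countdown) with 30 probes in each of three intervals relative to
  onset (early −2.25…−1.50 s, late −1.50…−0.75 s, after 0…0.75 s); two
  30-trial standing baselines without perturbation (probe window
  0.75–3.75 s with countdown, 0–3.75 s without); the second experiment
  appends a 30-trial sitting baseline.  The visual perturbation moves
  the front wall 5 m at 3 m/s, so each perturbation lasts 5/3 s.

* **Observers** answer yes/no by a Bernoulli draw from the Weibull
  detection probability at the presented integer intensity, with a true
  threshold per (condition, interval).  No sequential dependencies are
  modelled (the study found no practice effects).

* **Responses** are produced in closed loop: each adaptive track
  recommends an intensity, the observer responds, the track updates.
  Perturbation blocks run three interleaved independent tracks (one per
  probe interval), each seeded with the training-block estimate.

* **Sway traces** are a mean-reverting (Ornstein–Uhlenbeck) quiet-stance
  process plus, where the trial has a perturbation, a posterior-positive
  reactive excursion after onset, and — under low uncertainty — damped
  noise in the anticipatory window.  Missing-sample gaps and >15 cm
  outlier spikes can be injected at configurable rates (COP only, as in
  the recordings the pipeline mirrors).

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .kinematics import KinematicTrace, TRIAL_DURATION_S
from .quest import PsychometricModel, init_posterior, p_detect
from .thresholds import TrialRecord, estimate_block_threshold

__all__ = [
    "INTERVAL_WINDOWS",
    "ScheduledTrial",
    "SimulatedObserver",
    "SwayModel",
    "generate_schedule",
    "simulate_block",
    "simulate_session",
    "simulate_trace",
    "generate_fixture_suite",
]

LOW_UNCERTAINTY_ONSET_S = 3.0
HIGH_UNCERTAINTY_ONSET_RANGE_S = (2.25, 3.0)
PERTURBATION_DISTANCE_M = 5.0
PERTURBATION_SPEED_M_S = 3.0
PERTURBATION_DURATION_S = PERTURBATION_DISTANCE_M / PERTURBATION_SPEED_M_S  # 1.67 s
N_PROBES_PER_INTERVAL = 30

# probe windows in seconds relative to perturbation onset
INTERVAL_WINDOWS = {
    "early": (-2.25, -1.50),
    "late": (-1.50, -0.75),
    "after": (0.0, 0.75),
}
# probe windows relative to trial start for single-interval blocks
BASELINE_WINDOW_COUNTDOWN_S = (0.75, 3.75)
BASELINE_WINDOW_NO_COUNTDOWN_S = (0.0, 3.75)

STREAM_RATES_HZ = {"cop": 300.0, "head": 90.0}


@dataclass(frozen=True)
class ScheduledTrial:
    """One planned 7 s trial before any response is collected."""

    block_id: str
    block_type: str        # training | perturbation | baseline | sitting
    condition: str         # training | low | high | baseline_low | baseline_high | sitting
    trial_index: int       # 1-based within the block
    interval_label: str    # early | late | after | single
    onset: float           # perturbation (or nominal) onset, s from trial start
    probe_time: float      # s from trial start
    has_perturbation: bool
    perturbation_duration: float = PERTURBATION_DURATION_S


def _draw_onset(condition: str, rng: np.random.Generator) -> float:
    if condition in ("high", "baseline_high"):
        lo, hi = HIGH_UNCERTAINTY_ONSET_RANGE_S
        return float(rng.uniform(lo, hi))
    return LOW_UNCERTAINTY_ONSET_S


def _single_interval_block(
    block_id: str, block_type: str, condition: str,
    countdown: bool, rng: np.random.Generator,
) -> list[ScheduledTrial]:
    lo, hi = BASELINE_WINDOW_COUNTDOWN_S if countdown else BASELINE_WINDOW_NO_COUNTDOWN_S
    return [
        ScheduledTrial(
            block_id=block_id,
            block_type=block_type,
            condition=condition,
            trial_index=i + 1,
            interval_label="single",
            onset=_draw_onset(condition, rng),
            probe_time=float(rng.uniform(lo, hi)),
            has_perturbation=(block_type == "training"),
        )
        for i in range(N_PROBES_PER_INTERVAL)
    ]


def _perturbation_block(
    block_id: str, condition: str, rng: np.random.Generator
) -> list[ScheduledTrial]:
    labels = np.repeat(list(INTERVAL_WINDOWS), N_PROBES_PER_INTERVAL)
    rng.shuffle(labels)
    trials = []
    for i, lab in enumerate(labels):
        onset = _draw_onset(condition, rng)
        w0, w1 = INTERVAL_WINDOWS[lab]
        trials.append(
            ScheduledTrial(
                block_id=block_id,
                block_type="perturbation",
                condition=condition,
                trial_index=i + 1,
                interval_label=str(lab),
                onset=onset,
                probe_time=onset + float(rng.uniform(w0, w1)),
                has_perturbation=True,
            )
        )
    return trials


def generate_schedule(
    design: str = "exp1", seed: int | np.random.Generator = 0
) -> list[list[ScheduledTrial]]:
    """Block sequence for one participant of either experiment.

    ``exp1``: training, two perturbation blocks (order randomized), two
    standing baselines in the same condition order.  ``exp2``: the same
    plus a final sitting baseline.
    """
    if design not in ("exp1", "exp2"):
        raise ValueError(f"design must be 'exp1' or 'exp2', got {design!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = ["low", "high"] if rng.random() < 0.5 else ["high", "low"]
    blocks = [_single_interval_block("b1_training", "training", "training", True, rng)]
    for i, cond in enumerate(order):
        blocks.append(_perturbation_block(f"b{2 + i}_pert_{cond}", cond, rng))
    for i, cond in enumerate(order):
        blocks.append(
            _single_interval_block(
                f"b{4 + i}_base_{cond}", "baseline", f"baseline_{cond}",
                countdown=(cond == "low"), rng=rng,
            )
        )
    if design == "exp2":
        blocks.append(
            _single_interval_block("b6_sitting", "sitting", "sitting", True, rng)
        )
    return blocks


@dataclass
class SimulatedObserver:
    """Weibull yes/no observer with per-(condition, interval) thresholds.

    ``base_threshold`` is the observer's detection threshold in device
    units; ``interval_offsets`` shift it within perturbation blocks
    (e.g. ``{"after": -2}`` for better sensitivity right after onset) and
    ``condition_offsets`` shift whole conditions (e.g. ``{"sitting": -2}``).
    """

    base_threshold: float = 5.0
    model: PsychometricModel = field(default_factory=PsychometricModel)
    interval_offsets: dict[str, float] = field(default_factory=dict)
    condition_offsets: dict[str, float] = field(default_factory=dict)
    track_jitter_sd: float = 0.75  # block-to-block threshold fluctuation

    def threshold_for(
        self, condition: str, interval_label: str, jitter: float = 0.0
    ) -> float:
        t = self.base_threshold + jitter
        t += self.condition_offsets.get(condition, 0.0)
        if condition in ("low", "high"):
            t += self.interval_offsets.get(interval_label, 0.0)
        return max(t, 1.0)

    def respond(
        self, intensity: int, condition: str, interval_label: str,
        rng: np.random.Generator, jitter: float = 0.0,
    ) -> int:
        p = p_detect(
            float(intensity),
            self.threshold_for(condition, interval_label, jitter),
            self.model,
        )
        return int(rng.random() < p)


def simulate_block(
    block: list[ScheduledTrial],
    observer: SimulatedObserver,
    prior_mean: float,
    prior_sd: float,
    rng: np.random.Generator,
    *,
    n_points: int = 201,
    intensity_range: tuple[int, int] = (1, 200),
) -> list[TrialRecord]:
    """Run one block closed-loop: recommend -> respond -> update.

    Single-interval blocks run one adaptive track; perturbation blocks
    run three interleaved independent tracks, one per probe interval,
    each with its own prior copy and its own 1-based track index.
    """
    # fast closed-loop equivalent of recommend_intensity/update_posterior:
    # unnormalized log weights, likelihoods cached per integer intensity
    lo_i, hi_i = intensity_range
    model = observer.model

    class _Track:
        __slots__ = ("grid", "logw", "like_cache", "count", "raw", "quantized", "jitter")

        def __init__(self):
            post = init_posterior(
                prior_mean, prior_sd, model,
                n_points=n_points, intensity_range=intensity_range,
            )
            self.grid = post.threshold_grid
            self.logw = post.log_weights
            self.like_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            self.count = 0
            self._refresh()

        def _refresh(self):
            w = np.exp(self.logw - self.logw.max())
            self.raw = float((w @ self.grid) / w.sum())
            q = int(np.sign(self.raw) * np.floor(abs(self.raw) + 0.5))
            self.quantized = min(max(q, lo_i), hi_i)

        def update(self, intensity: int, response: int):
            if intensity not in self.like_cache:
                p = np.asarray(p_detect(float(intensity), self.grid, model))
                with np.errstate(divide="ignore"):
                    self.like_cache[intensity] = (
                        np.maximum(np.log(p), -745.0),
                        np.maximum(np.log1p(-p), -745.0),
                    )
            log_yes, log_no = self.like_cache[intensity]
            self.logw = self.logw + (log_yes if response else log_no)
            self._refresh()

    tracks: dict[str, _Track] = {}
    records: list[TrialRecord] = []
    for trial in block:
        lab = trial.interval_label
        track = tracks.get(lab)
        if track is None:
            track = tracks[lab] = _Track()
            track.jitter = (
                rng.normal(0.0, observer.track_jitter_sd)
                if observer.track_jitter_sd > 0 else 0.0
            )
        presented = track.quantized
        response = observer.respond(presented, trial.condition, lab, rng, track.jitter)
        track.update(presented, response)
        track.count += 1
        records.append(
            TrialRecord(
                trial_index=track.count,
                block_id=trial.block_id,
                condition=trial.condition,
                interval_label=lab,
                presented_intensity=presented,
                response=response,
                raw_recommendation=track.raw,
                quantized_recommendation=track.quantized,
            )
        )
    return records


def simulate_session(
    schedule: list[list[ScheduledTrial]],
    observer: SimulatedObserver,
    prior_mean: float,
    prior_sd: float,
    seed: int | np.random.Generator = 0,
    *,
    block_prior_sd: float | None = 0.5,
    n_points: int = 201,
    intensity_range: tuple[int, int] = (1, 200),
) -> dict[str, list[TrialRecord]]:
    """All blocks of one participant.

    The training block uses the configured prior (a stand-in for a pilot
    estimate); every later block's tracks are seeded with the training
    block's converged threshold as prior mean (falling back to the last
    training recommendation when training never reached a valid plateau).
    ``block_prior_sd`` is the prior SD of those later tracks — tighter
    than the pilot prior, since the training posterior is itself already
    concentrated; ``None`` reuses ``prior_sd``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    logs: dict[str, list[TrialRecord]] = {}
    block_prior = prior_mean
    sd = prior_sd
    for block in schedule:
        records = simulate_block(
            block, observer, block_prior, sd, rng,
            n_points=n_points, intensity_range=intensity_range,
        )
        logs[block[0].block_id] = records
        if block[0].block_type == "training":
            est = estimate_block_threshold(records)
            if est.valid and est.value is not None:
                block_prior = float(est.value)
            else:
                block_prior = float(records[-1].quantized_recommendation)
            if block_prior_sd is not None:
                sd = block_prior_sd
    return logs


@dataclass
class SwayModel:
    """Generative quiet-stance + perturbation-response sway process.

    Quiet stance is a zero-mean Ornstein–Uhlenbeck process with
    mean-reversion rate ``theta`` (1/s) and stationary SD per stream
    (metres).  ``anticipatory_damping`` scales the innovation noise in
    the 2.25 s before a *predictable* (low-uncertainty) perturbation.
    The reactive excursion is a posterior-positive raised-cosine ramp of
    amplitude ``reactive_amplitude`` beginning ``reactive_latency`` after
    onset, rising over ``reactive_rise``, holding for ``reactive_hold``,
    optionally preceded by a small anterior dip (``anterior_dip_frac``).
    ``gap_rate`` / ``outlier_rate`` inject, per COP trial, a >=100 ms
    missing run or a >15 cm spike.
    """

    theta: float = 1.0
    stationary_sd: dict[str, float] = field(
        default_factory=lambda: {"cop": 0.005, "head": 0.003}
    )
    anticipatory_damping: float = 0.5
    reactive_amplitude: dict[str, float] = field(
        default_factory=lambda: {"cop": 0.020, "head": 0.010}
    )
    reactive_latency: float = 0.15
    reactive_rise: float = 0.8
    reactive_hold: float = 1.0
    anterior_dip_frac: float = 0.0
    gap_rate: float = 0.0
    outlier_rate: float = 0.0

    def excursion(self, t: np.ndarray, onset: float, stream: str) -> np.ndarray:
        """Deterministic reactive component added to the noise process."""
        amp = self.reactive_amplitude[stream]
        tau = t - onset - self.reactive_latency
        rise = np.clip(tau / self.reactive_rise, 0.0, 1.0)
        ramp = 0.5 * (1.0 - np.cos(np.pi * rise))
        fall_start = self.reactive_rise + self.reactive_hold
        fall = np.clip((tau - fall_start) / self.reactive_rise, 0.0, 1.0)
        y = amp * ramp * (1.0 - 0.5 * (1.0 - np.cos(np.pi * fall)))
        y[tau < 0] = 0.0
        if self.anterior_dip_frac > 0:
            dip_t = np.clip(tau / self.reactive_latency, 0.0, 1.0)
            y -= amp * self.anterior_dip_frac * np.sin(np.pi * dip_t) * (tau >= 0)
        return y


def simulate_trace(
    sway: SwayModel,
    trial: ScheduledTrial,
    stream: str,
    seed: int | np.random.Generator = 0,
) -> KinematicTrace:
    """One trial's anterior–posterior trace at the stream's native rate."""
    rate = STREAM_RATES_HZ[stream]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(TRIAL_DURATION_S * rate))
    t = np.arange(n) / rate
    dt = 1.0 / rate
    s = sway.stationary_sd[stream]
    phi = np.exp(-sway.theta * dt)
    innov_sd = s * np.sqrt(1.0 - phi**2)
    # per-sample innovation scaling: damped in the anticipatory window of
    # predictable (countdown) perturbation trials
    scale = np.ones(n)
    if trial.has_perturbation and trial.condition in ("training", "low"):
        in_window = (t >= trial.onset - 2.25) & (t < trial.onset)
        scale[in_window] = sway.anticipatory_damping
    eps = rng.standard_normal(n) * innov_sd * scale
    x0 = rng.standard_normal() * s
    # AR(1) recursion x[k] = phi*x[k-1] + eps[k] as an IIR filter
    x = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))[0]
    if trial.has_perturbation:
        x = x + sway.excursion(t, trial.onset, stream)
    if stream == "cop":
        if sway.outlier_rate > 0 and rng.random() < sway.outlier_rate:
            i = int(rng.integers(0, n))
            x[i] = 0.2 * (1 if rng.random() < 0.5 else -1)
        if sway.gap_rate > 0 and rng.random() < sway.gap_rate:
            gap = int(rng.uniform(0.10, 0.30) * rate)
            i = int(rng.integers(0, max(1, n - gap)))
            x[i : i + gap] = np.nan
    return KinematicTrace(samples=x, rate=rate, onset=trial.onset, stream=stream)


def schedule_to_frame(schedule: list[list[ScheduledTrial]]):
    """Long-format DataFrame view of a schedule (one row per trial)."""
    import pandas as pd

    rows = [vars(tr) for block in schedule for tr in block]
    return pd.DataFrame(rows)


def records_to_frame(logs: dict[str, list[TrialRecord]]):
    """Long-format DataFrame of the session log CSV schema."""
    import pandas as pd

    rows = [vars(r) for recs in logs.values() for r in recs]
    return pd.DataFrame(rows)


def generate_fixture_suite(
    seed: int, out_dir, n_subjects: int = 2, design: str = "exp1"
):
    """Small deterministic CSV/JSON fixtures for regression tests.

    Writes, per subject, a schedule table and a closed-loop session log
    using a stationary observer; byte-identical for identical seeds.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    meta = {"design": design, "seed": seed, "n_subjects": n_subjects, "subjects": []}
    for s in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        schedule = generate_schedule(design, rng)
        obs = SimulatedObserver(base_threshold=max(2.5, float(rng.normal(5.0, 1.2))))
        logs = simulate_session(schedule, obs, prior_mean=5.0, prior_sd=1.5, seed=rng)
        schedule_to_frame(schedule).to_csv(out / f"s{s + 1:02d}_schedule.csv", index=False)
        records_to_frame(logs).to_csv(out / f"s{s + 1:02d}_trials.csv", index=False)
        meta["subjects"].append(
            {"id": f"s{s + 1:02d}", "seed": sub_seed,
             "true_threshold": obs.base_threshold}
        )
    (out / "fixture_meta.json").write_text(json.dumps(meta, indent=2))
    return meta
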
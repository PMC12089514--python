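"""End-to-end orchestration: simulate or load a session set, determine
thresholds, compute sway metrics, run the statistical layer, and emit a
machine-readable results bundle.

The configuration is a validated pydantic model whose defaults reproduce
the study's analysis parameters (100 ms gap rule, 15 cm outlier fence,
100 ms smoothing, 2.25 s anticipatory and 3.5 s reactive windows,
3.5xIQR exclusion, Weibull slope beta = 3.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import kinematics as kin
from . import synthetic as syn
from .quest import PsychometricModel
from .stats import (
    StatResult,
    holm_correct,
    iqr_exclude,
    one_sample_t,
    paired_t,
    rm_anova_3x2,
)
from .thresholds import (
    INTERVALS,
    ThresholdEstimate,
    TrialRecord,
    estimate_block_threshold,
)

logger = logging.getLogger("swayquest")

__all__ = ["AnalysisConfig", "ResultsBundle", "run_experiment", "validate_inputs"]


class QuestSettings(BaseModel):
    beta: float = 3.5
    gamma: float = 0.01
    delta: float = 0.01
    intensity_scale: str = "log10"
    prior_mean: float = 5.0
    prior_sd: float = 1.5
    block_prior_sd: float = 0.5
    grid_points: int = Field(201, ge=100)
    grid_span_sd: float = Field(5.0, ge=4.0)
    intensity_min: int = 1
    intensity_max: int = 200

    def model_object(self) -> PsychometricModel:
        return PsychometricModel(
            beta=self.beta, gamma=self.gamma, delta=self.delta,
            intensity_scale=self.intensity_scale,
        )


class CleaningSettings(BaseModel):
    gap_ms: float = 100.0
    outlier_cm: float = 15.0
    smoothing_ms: float = 100.0
    anticipatory_window_s: float = 2.25
    reactive_window_s: float = 3.5


class ObserverSettings(BaseModel):
    """Population of simulated observers (device units)."""

    base_threshold_mean: float = 5.0
    base_threshold_sd: float = 1.2
    min_threshold: float = 2.5
    track_jitter_sd: float = 0.75
    interval_offsets: dict[str, float] = Field(default_factory=dict)
    condition_offsets: dict[str, float] = Field(default_factory=dict)


class SwaySettings(BaseModel):
    theta: float = 1.0
    cop_sd_m: float = 0.005
    head_sd_m: float = 0.003
    anticipatory_damping: float = 0.5
    cop_reactive_m: float = 0.020
    head_reactive_m: float = 0.010
    gap_rate: float = 0.0
    outlier_rate: float = 0.0

    def model_object(self) -> syn.SwayModel:
        return syn.SwayModel(
            theta=self.theta,
            stationary_sd={"cop": self.cop_sd_m, "head": self.head_sd_m},
            anticipatory_damping=self.anticipatory_damping,
            reactive_amplitude={"cop": self.cop_reactive_m, "head": self.head_reactive_m},
            gap_rate=self.gap_rate,
            outlier_rate=self.outlier_rate,
        )


class StatSettings(BaseModel):
    iqr_multiplier: float = 3.5
    alpha: float = 0.05


class AnalysisConfig(BaseModel):
    """Full experiment/analysis configuration."""

    design: str = "exp1"
    n_subjects: int = Field(20, ge=1)
    quest: QuestSettings = Field(default_factory=QuestSettings)
    cleaning: CleaningSettings = Field(default_factory=CleaningSettings)
    observers: ObserverSettings = Field(default_factory=ObserverSettings)
    sway: SwaySettings = Field(default_factory=SwaySettings)
    stats: StatSettings = Field(default_factory=StatSettings)
    seed: int = 0
    with_kinematics: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.design not in ("exp1", "exp2"):
            raise ValueError("design must be 'exp1' or 'exp2'")
        if self.quest.intensity_min < 1:
            raise ValueError("intensity_min must be >= 1")
        return self

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls.model_validate_json(Path(path).read_text())


@dataclass
class ResultsBundle:
    """Everything one run produces, ready for CSV/JSON export."""

    config: AnalysisConfig
    thresholds: pd.DataFrame           # one row per adaptive track
    deltas: pd.DataFrame               # subject x condition x interval
    metrics: pd.DataFrame              # kinematic metrics (may be empty)
    tests: list[StatResult] = field(default_factory=list)
    anova: dict[str, StatResult] = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        self.deltas.to_csv(out / "delta_thresholds.csv", index=False)
        if not self.metrics.empty:
            self.metrics.to_csv(out / "sway_metrics.csv", index=False)
        report = {
            "tests": [vars(t) for t in self.tests],
            "anova": {k: vars(v) for k, v in self.anova.items()},
            "exclusions": self.exclusions,
            "summary": self.summary,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        (out / "config.json").write_text(self.config.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# threshold layer
# ---------------------------------------------------------------------------

_BASELINE_OF = {"low": "baseline_low", "high": "baseline_high"}


def _session_thresholds(
    subject: str, logs: dict[str, list[TrialRecord]]
) -> list[ThresholdEstimate]:
    """One estimate per adaptive track of one participant's session."""
    ests: list[ThresholdEstimate] = []
    for records in logs.values():
        by_track: dict[str, list[TrialRecord]] = {}
        for r in records:
            by_track.setdefault(r.interval_label, []).append(r)
        for track in by_track.values():
            ests.append(estimate_block_threshold(track))
    return ests


def _thresholds_frame(all_estimates: dict[str, list[ThresholdEstimate]]) -> pd.DataFrame:
    rows = []
    for subject, ests in all_estimates.items():
        for e in ests:
            rows.append(
                dict(
                    participant=subject,
                    block_id=e.block_id,
                    condition=e.condition,
                    interval=e.interval_label,
                    threshold=e.value,
                    convergence_trial=e.convergence_trial,
                    n_trials_to_estimate=e.n_trials_to_estimate,
                    valid=e.valid,
                )
            )
    return pd.DataFrame(rows)


def _delta_frame(thresholds: pd.DataFrame, design: str) -> pd.DataFrame:
    """Baseline-normalized Δthresholds, one row per (subject, cond, interval).

    Experiment 1 normalizes each perturbation condition against its
    matching standing baseline; experiment 2 against the sitting
    baseline.  An invalid baseline voids all deltas that depend on it.
    """
    rows = []
    for subject, sub in thresholds.groupby("participant"):
        def valid_value(cond):
            r = sub[(sub.condition == cond) & sub.valid]
            return float(r.threshold.iloc[0]) if len(r) == 1 else None

        for cond in ("low", "high"):
            if design == "exp2":
                base = valid_value("sitting")
            else:
                base = valid_value(_BASELINE_OF[cond])
            for interval in INTERVALS:
                r = sub[(sub.condition == cond) & (sub.interval == interval) & sub.valid]
                thr = float(r.threshold.iloc[0]) if len(r) == 1 else None
                delta = thr - base if (thr is not None and base is not None) else np.nan
                rows.append(
                    dict(
                        participant=subject, condition=cond, interval=interval,
                        threshold=thr if thr is not None else np.nan,
                        baseline=base if base is not None else np.nan,
                        delta=delta,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinematic layer
# ---------------------------------------------------------------------------


def _simulate_kinematic_metrics(
    config: AnalysisConfig,
    schedule: list[list[syn.ScheduledTrial]],
    logs: dict[str, list[TrialRecord]],
    estimates: list[ThresholdEstimate],
    rng: np.random.Generator,
) -> list[dict]:
    """Per-trial traces -> cleaned metrics, restricted to threshold trials.

    Trials beyond a track's convergence trial, and trials of invalid
    tracks, are excluded from the kinematic averages, mirroring the
    linked trial-selection rule.  Gap-dropped trials are excluded too.
    """
    cl = config.cleaning
    sway = config.sway.model_object()
    conv: dict[tuple[str, str], ThresholdEstimate] = {
        (e.block_id, e.interval_label): e for e in estimates
    }
    rows = []
    for block in schedule:
        btype = block[0].block_type
        if btype == "training" or block[0].condition == "sitting":
            continue
        records = logs[block[0].block_id]
        for trial, record in zip(block, records):
            est = conv.get((trial.block_id, trial.interval_label))
            keep = (
                est is not None
                and est.valid
                and record.trial_index <= (est.convergence_trial or 0)
            )
            if not keep:
                continue
            for stream in ("cop", "head"):
                trace = syn.simulate_trace(sway, trial, stream, rng)
                cleaned = kin.clean_trace(
                    trace, gap_s=cl.gap_ms / 1000.0,
                    limit_m=cl.outlier_cm / 100.0,
                    window_s=cl.smoothing_ms / 1000.0,
                )
                if cleaned is None:
                    continue
                rows.append(
                    dict(
                        block_id=trial.block_id,
                        condition=trial.condition,
                        stream=stream,
                        trial_index=record.trial_index,
                        anticipatory=kin.anticipatory_metric(
                            cleaned, window_s=cl.anticipatory_window_s
                        ),
                        reactive=kin.reactive_metric(
                            cleaned, window_s=cl.reactive_window_s
                        ),
                    )
                )
    return rows


def _load_kinematic_metrics(
    config: AnalysisConfig,
    subject: str,
    kinematics: pd.DataFrame,
    schedule: pd.DataFrame,
    estimates: list[ThresholdEstimate],
) -> list[dict]:
    """Metrics for recorded traces, restricted to threshold trials.

    ``schedule`` maps (block_id, trial_index) to onset, condition and
    interval label; the track-local trial rank (order within the block's
    interval) links each trial to its adaptive track's convergence
    point.
    """
    cl = config.cleaning
    conv: dict[tuple[str, str], ThresholdEstimate] = {
        (e.block_id, e.interval_label): e for e in estimates
    }
    sched = schedule[schedule.participant == subject].copy()
    sched = sched.sort_values(["block_id", "trial_index"])
    sched["track_rank"] = sched.groupby(["block_id", "interval_label"]).cumcount() + 1
    meta = sched.set_index(["block_id", "trial_index"])
    rows = []
    kin_sub = kinematics[kinematics.participant == subject]
    for (block_id, trial, stream), g in kin_sub.groupby(["block_id", "trial", "stream"]):
        key = (str(block_id), int(trial))
        if key not in meta.index:
            continue
        info = meta.loc[key]
        est = conv.get((str(block_id), str(info.interval_label)))
        keep = (
            est is not None and est.valid
            and int(info.track_rank) <= (est.convergence_trial or 0)
        )
        if not keep:
            continue
        g = g.sort_values("t")
        rate = 1.0 / float(np.median(np.diff(g.t.to_numpy())))
        trace = kin.KinematicTrace(
            samples=g.x.to_numpy(dtype=float), rate=rate,
            onset=float(info.onset), stream=str(stream),
        )
        cleaned = kin.clean_trace(
            trace, gap_s=cl.gap_ms / 1000.0,
            limit_m=cl.outlier_cm / 100.0,
            window_s=cl.smoothing_ms / 1000.0,
        )
        if cleaned is None:
            continue
        rows.append(
            dict(
                block_id=str(block_id),
                condition=str(info.condition),
                stream=str(stream),
                trial_index=int(info.track_rank),
                anticipatory=kin.anticipatory_metric(
                    cleaned, window_s=cl.anticipatory_window_s
                ),
                reactive=kin.reactive_metric(cleaned, window_s=cl.reactive_window_s),
            )
        )
    return rows


def _metrics_frame(per_subject_rows: dict[str, list[dict]]) -> pd.DataFrame:
    """Trial-averaged, baseline-normalized metrics per subject/condition/stream."""
    rows = []
    for subject, trial_rows in per_subject_rows.items():
        if not trial_rows:
            continue
        df = pd.DataFrame(trial_rows)
        means = df.groupby(["condition", "stream"])[["anticipatory", "reactive"]].mean()
        for cond in ("low", "high"):
            for stream in ("cop", "head"):
                if (cond, stream) not in means.index:
                    continue
                m = means.loc[(cond, stream)]
                base_key = (_BASELINE_OF[cond], stream)
                base = means.loc[base_key] if base_key in means.index else None
                rows.append(
                    dict(
                        participant=subject, condition=cond, stream=stream,
                        anticipatory=m.anticipatory, reactive=m.reactive,
                        anticipatory_norm=kin.normalize_metric_to_baseline(
                            m.anticipatory, None if base is None else base.anticipatory
                        ),
                        reactive_norm=kin.normalize_metric_to_baseline(
                            m.reactive, None if base is None else base.reactive
                        ),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics layer
# ---------------------------------------------------------------------------


def _apply_iqr_with_propagation(
    deltas: pd.DataFrame, thresholds: pd.DataFrame, design: str, multiplier: float
) -> tuple[pd.DataFrame, dict]:
    """3.5xIQR exclusion per condition, with linked baseline removal.

    Outlying deltas are dropped from their own (condition, interval)
    cell; an outlying *baseline* threshold drops all deltas normalized
    by it, since normalization is impossible without the baseline.
    """
    deltas = deltas.copy()
    deltas["retained"] = ~deltas.delta.isna()
    log: dict[str, dict] = {}

    def run_fence(values: pd.Series, label: str) -> pd.Index:
        finite = values.dropna()
        if len(finite) < 4:
            return pd.Index([])
        retain, info = iqr_exclude(finite.to_numpy(), multiplier)
        log[label] = info
        return finite.index[~retain]

    # per-condition delta cells
    for (cond, interval), cell in deltas.groupby(["condition", "interval"]):
        bad = run_fence(cell.delta, f"delta_{cond}_{interval}")
        deltas.loc[bad, "retained"] = False

    # baseline threshold sets, with linked removal
    base_conds = ["sitting"] if design == "exp2" else ["baseline_low", "baseline_high"]
    for bcond in base_conds:
        b = thresholds[(thresholds.condition == bcond) & thresholds.valid]
        series = b.set_index("participant").threshold.astype(float)
        bad_subjects = run_fence(series.reset_index(drop=True), f"baseline_{bcond}")
        excluded = series.reset_index().loc[bad_subjects, "participant"].tolist()
        if excluded:
            if design == "exp2":
                mask = deltas.participant.isin(excluded)
            else:
                cond = "low" if bcond == "baseline_low" else "high"
                mask = deltas.participant.isin(excluded) & (deltas.condition == cond)
            deltas.loc[mask, "retained"] = False
            log[f"baseline_{bcond}"]["propagated_subjects"] = excluded
    return deltas, log


def _anova_cells(deltas: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    subjects = sorted(deltas.participant.unique())
    cells = np.full((len(subjects), 3, 2), np.nan)
    for si, s in enumerate(subjects):
        for ii, interval in enumerate(INTERVALS):
            for ci, cond in enumerate(("low", "high")):
                row = deltas[
                    (deltas.participant == s)
                    & (deltas.interval == interval)
                    & (deltas.condition == cond)
                    & deltas.retained
                ]
                if len(row) == 1:
                    cells[si, ii, ci] = row.delta.iloc[0]
    return cells, subjects


def _threshold_stats(
    deltas: pd.DataFrame, design: str, alpha: float
) -> tuple[list[StatResult], dict[str, StatResult]]:
    tests: list[StatResult] = []
    sided = "two" if design == "exp1" else "greater"
    for cond in ("low", "high"):
        for interval in INTERVALS:
            cell = deltas[
                (deltas.condition == cond) & (deltas.interval == interval) & deltas.retained
            ].delta.dropna()
            if len(cell) >= 2 and np.ptp(cell) > 0:
                tests.append(
                    one_sample_t(
                        cell, 0.0, sided, name=f"delta_vs_zero[{cond},{interval}]"
                    )
                )
    cells, _ = _anova_cells(deltas)
    anova: dict[str, StatResult] = {}
    try:
        anova = rm_anova_3x2(cells)
    except ValueError as err:
        logger.warning("RM-ANOVA skipped: %s", err)

    # post-hoc paired comparisons between intervals (collapsed over
    # uncertainty), Holm-corrected
    posthoc: list[StatResult] = []
    complete = cells[~np.isnan(cells).any(axis=(1, 2))]
    if complete.shape[0] >= 3:
        interval_means = complete.mean(axis=2)  # (n, 3)
        pairs = [("early", "late", 0, 1), ("late", "after", 1, 2), ("early", "after", 0, 2)]
        for a_lab, b_lab, i, j in pairs:
            try:
                posthoc.append(
                    paired_t(
                        interval_means[:, i], interval_means[:, j], "two",
                        name=f"posthoc[{a_lab}-{b_lab}]",
                    )
                )
            except ZeroDivisionError:
                pass
        if posthoc:
            adj = holm_correct([t.p for t in posthoc])
            posthoc = [
                StatResult(**{**vars(t), "p_adjusted": float(p)})
                for t, p in zip(posthoc, adj)
            ]
    return tests + posthoc, anova


def _kinematic_stats(metrics: pd.DataFrame) -> list[StatResult]:
    """Anticipatory and reactive sway vs quiet-stance baseline.

    Anticipatory: one-sided (reduction) under low uncertainty, two-sided
    under high; reactive: one-sided (increase) for both conditions.
    """
    tests: list[StatResult] = []
    if metrics.empty:
        return tests
    for stream in ("cop", "head"):
        for cond in ("low", "high"):
            sub = metrics[(metrics.condition == cond) & (metrics.stream == stream)]
            ant = sub.anticipatory_norm.dropna()
            rea = sub.reactive_norm.dropna()
            if len(ant) >= 2 and np.ptp(ant) > 0:
                tests.append(
                    one_sample_t(
                        ant, 0.0, "less" if cond == "low" else "two",
                        name=f"anticipatory_vs_baseline[{cond},{stream}]",
                    )
                )
            if len(rea) >= 2 and np.ptp(rea) > 0:
                tests.append(
                    one_sample_t(
                        rea, 0.0, "greater",
                        name=f"reactive_vs_baseline[{cond},{stream}]",
                    )
                )
    return tests


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------


def run_experiment(
    config: AnalysisConfig,
    mode: str = "simulate",
    trials: pd.DataFrame | None = None,
    kinematics: pd.DataFrame | None = None,
    schedule: pd.DataFrame | None = None,
) -> ResultsBundle:
    """Run the full analysis, simulating sessions or loading a trial log.

    In ``simulate`` mode, ``config.n_subjects`` observers are drawn from
    the configured population and run closed-loop through the design; in
    ``load`` mode, ``trials`` must hold the session-log CSV schema
    (participant, trial_index, block_id, condition, interval_label,
    presented_intensity, response, raw_recommendation,
    quantized_recommendation).  Recorded kinematics can be supplied as a
    long-format frame (participant, block_id, trial, stream, t, x)
    together with a ``schedule`` frame (participant, block_id,
    trial_index, interval_label, condition, onset) that provides each
    trial's perturbation onset and probe-interval label.
    """
    if mode not in ("simulate", "load"):
        raise ValueError("mode must be 'simulate' or 'load'")
    all_est: dict[str, list[ThresholdEstimate]] = {}
    metric_rows: dict[str, list[dict]] = {}

    if mode == "simulate":
        master = np.random.default_rng(config.seed)
        model = config.quest.model_object()
        for s in range(config.n_subjects):
            subject = f"s{s + 1:02d}"
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            schedule = syn.generate_schedule(config.design, rng)
            obs = syn.SimulatedObserver(
                base_threshold=max(
                    config.observers.min_threshold,
                    float(rng.normal(
                        config.observers.base_threshold_mean,
                        config.observers.base_threshold_sd,
                    )),
                ),
                model=model,
                track_jitter_sd=config.observers.track_jitter_sd,
                interval_offsets=dict(config.observers.interval_offsets),
                condition_offsets=dict(config.observers.condition_offsets),
            )
            logs = syn.simulate_session(
                schedule, obs,
                prior_mean=config.quest.prior_mean,
                prior_sd=config.quest.prior_sd,
                seed=rng,
                block_prior_sd=config.quest.block_prior_sd,
                n_points=config.quest.grid_points,
                intensity_range=(config.quest.intensity_min, config.quest.intensity_max),
            )
            ests = _session_thresholds(subject, logs)
            all_est[subject] = ests
            if config.with_kinematics:
                metric_rows[subject] = _simulate_kinematic_metrics(
                    config, schedule, logs, ests, rng
                )
    else:
        if trials is None:
            raise ValueError("load mode requires a trials DataFrame")
        for subject, sub in trials.groupby("participant"):
            logs: dict[str, list[TrialRecord]] = {}
            for block_id, b in sub.groupby("block_id", sort=False):
                logs[str(block_id)] = [
                    TrialRecord(
                        trial_index=int(r.trial_index),
                        block_id=str(r.block_id),
                        condition=str(r.condition),
                        interval_label=str(r.interval_label),
                        presented_intensity=int(r.presented_intensity),
                        response=int(r.response),
                        raw_recommendation=float(r.raw_recommendation),
                        quantized_recommendation=int(r.quantized_recommendation),
                    )
                    for r in b.itertuples()
                ]
            all_est[str(subject)] = _session_thresholds(str(subject), logs)

    if mode == "load" and kinematics is not None:
        if schedule is None:
            raise ValueError("loading kinematics requires a schedule frame "
                             "with per-trial onsets and interval labels")
        for subject, ests in all_est.items():
            metric_rows[subject] = _load_kinematic_metrics(
                config, subject, kinematics, schedule, ests
            )

    thresholds = _thresholds_frame(all_est)
    deltas = _delta_frame(thresholds, config.design)
    deltas, excl_log = _apply_iqr_with_propagation(
        deltas, thresholds, config.design, config.stats.iqr_multiplier
    )
    tests, anova = _threshold_stats(deltas, config.design, config.stats.alpha)
    metrics = _metrics_frame(metric_rows)
    tests.extend(_kinematic_stats(metrics))

    if config.design == "exp2":
        tests.extend(_standing_vs_sitting(thresholds))

    valid = thresholds[thresholds.valid]
    summary = {
        "design": config.design,
        "seed": config.seed,
        "n_subjects": int(thresholds.participant.nunique()),
        "n_threshold_estimates": int(len(thresholds)),
        "n_valid_estimates": int(len(valid)),
        "invalid_rate": float(1.0 - len(valid) / max(len(thresholds), 1)),
        "mean_trials_to_estimate": float(valid.n_trials_to_estimate.mean())
        if len(valid) else None,
        "sd_trials_to_estimate": float(valid.n_trials_to_estimate.std(ddof=1))
        if len(valid) > 1 else None,
    }
    return ResultsBundle(
        config=config, thresholds=thresholds, deltas=deltas, metrics=metrics,
        tests=tests, anova=anova, exclusions=excl_log, summary=summary,
    )


def _standing_vs_sitting(thresholds: pd.DataFrame) -> list[StatResult]:
    """Two-sided paired t: averaged standing baselines vs sitting baseline."""
    stand, sit = [], []
    for _, sub in thresholds.groupby("participant"):
        s_rows = sub[sub.condition.isin(["baseline_low", "baseline_high"]) & sub.valid]
        t_rows = sub[(sub.condition == "sitting") & sub.valid]
        if len(s_rows) == 2 and len(t_rows) == 1:
            stand.append(s_rows.threshold.astype(float).mean())
            sit.append(float(t_rows.threshold.iloc[0]))
    if len(stand) < 2:
        return []
    try:
        return [paired_t(stand, sit, "two", name="standing_vs_sitting")]
    except ZeroDivisionError:
        return []


def validate_inputs(
    trials: pd.DataFrame | None = None, kinematics: pd.DataFrame | None = None
) -> list[dict]:
    """Schema and design-conformity diagnostics (warnings, not errors)."""
    diags: list[dict] = []

    def add(level, message):
        diags.append({"level": level, "message": message})

    if trials is not None:
        required = {
            "participant", "trial_index", "block_id", "condition",
            "interval_label", "presented_intensity", "response",
            "raw_recommendation", "quantized_recommendation",
        }
        missing = required - set(trials.columns)
        if missing:
            add("error", f"trial log missing columns: {sorted(missing)}")
        else:
            for (subject, block), b in trials.groupby(["participant", "block_id"]):
                n = len(b)
                labels = set(b.interval_label)
                expect = 90 if labels & {"early", "late", "after"} else 30
                if n != expect:
                    add("warning", f"{subject}/{block}: {n} trials, expected {expect}")
                if not set(b.response.unique()) <= {0, 1}:
                    add("error", f"{subject}/{block}: non-binary responses")
    if kinematics is not None:
        required = {"participant", "block_id", "trial", "stream", "t", "x"}
        missing = required - set(kinematics.columns)
        if missing:
            add("error", f"kinematics missing columns: {sorted(missing)}")
        else:
            for (subject, block, trial, stream), g in kinematics.groupby(
                ["participant", "block_id", "trial", "stream"]
            ):
                t = np.sort(g.t.to_numpy())
                if len(t) < 2:
                    add("warning", f"{subject}/{block}/{trial}/{stream}: too few samples")
                    continue
                rate = 1.0 / np.median(np.diff(t))
                expect = syn.STREAM_RATES_HZ.get(str(stream))
                if expect and abs(rate - expect) > 1.0:
                    add(
                        "error",
                        f"{subject}/{block}/{trial}/{stream}: sampling rate "
                        f"{rate:.1f} Hz, expected {expect:.0f}",
                    )
                n_missing = int(g.x.isna().sum())
                if n_missing:
                    add("info", f"{subject}/{block}/{trial}/{stream}: "
                                f"{n_missing} missing samples")
    if not diags:
        add("info", "all checks passed")
    return diags
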
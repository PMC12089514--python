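"""Schedule, observer, closed-loop and trace generator tests."""

import numpy as np
import pytest
from scipy import stats as sps

from swayquest.kinematics import clean_trace, exclude_gapped_trials, reactive_metric
from swayquest.quest import PsychometricModel
from swayquest.synthetic import (
    INTERVAL_WINDOWS,
    PERTURBATION_DURATION_S,
    ScheduledTrial,
    SimulatedObserver,
    SwayModel,
    generate_fixture_suite,
    generate_schedule,
    records_to_frame,
    simulate_session,
    simulate_trace,
)
from swayquest.thresholds import estimate_block_threshold


class TestSchedule:
    def test_exp1_block_structure(self):
        blocks = generate_schedule("exp1", 0)
        assert len(blocks) == 5
        assert [len(b) for b in blocks] == [30, 90, 90, 30, 30]

    def test_exp2_appends_sitting_baseline(self):
        blocks = generate_schedule("exp2", 0)
        assert len(blocks) == 6
        assert blocks[-1][0].condition == "sitting"
        assert len(blocks[-1]) == 30

    def test_perturbation_block_has_thirty_probes_per_interval(self):
        blocks = generate_schedule("exp1", 1)
        pert = [b for b in blocks if b[0].block_type == "perturbation"][0]
        labels = [t.interval_label for t in pert]
        assert len(pert) == 90
        for lab in ("early", "late", "after"):
            assert labels.count(lab) == 30

    def test_perturbation_lasts_five_thirds_seconds(self):
        blocks = generate_schedule("exp1", 2)
        durations = {t.perturbation_duration for b in blocks for t in b}
        assert durations == {PERTURBATION_DURATION_S}
        assert PERTURBATION_DURATION_S == pytest.approx(5.0 / 3.0)

    def test_low_uncertainty_onset_fixed_at_three_seconds(self):
        for seed in range(5):
            blocks = generate_schedule("exp1", seed)
            for b in blocks:
                for t in b:
                    if t.condition in ("low", "training", "baseline_low"):
                        assert t.onset == 3.0

    def test_high_uncertainty_onsets_uniform(self):
        onsets = []
        rng = np.random.default_rng(3)
        while len(onsets) < 10_000:
            for b in generate_schedule("exp1", rng):
                onsets += [t.onset for t in b if t.condition == "high"]
        onsets = np.asarray(onsets[:10_000])
        assert onsets.min() >= 2.25 and onsets.max() <= 3.0
        stat = sps.kstest(onsets, sps.uniform(loc=2.25, scale=0.75).cdf)
        assert stat.pvalue > 0.01

    def test_probe_times_fall_in_their_interval_windows(self):
        blocks = generate_schedule("exp1", 4)
        for b in blocks:
            for t in b:
                if t.interval_label in INTERVAL_WINDOWS:
                    w0, w1 = INTERVAL_WINDOWS[t.interval_label]
                    assert t.onset + w0 <= t.probe_time < t.onset + w1
                else:
                    lo = 0.75 if t.condition in ("training", "baseline_low", "sitting") else 0.0
                    assert lo <= t.probe_time <= 3.75

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule("exp3", 0)


class TestObserver:
    def test_far_suprathreshold_always_detected(self, rng):
        obs = SimulatedObserver(
            base_threshold=5.0,
            model=PsychometricModel(gamma=0.0, delta=0.0),
            track_jitter_sd=0.0,
        )
        assert all(obs.respond(60, "low", "early", rng) for _ in range(200))

    def test_condition_and_interval_offsets_applied(self):
        obs = SimulatedObserver(
            base_threshold=6.0,
            interval_offsets={"after": -2.0},
            condition_offsets={"sitting": -1.0},
        )
        assert obs.threshold_for("low", "after") == 4.0
        assert obs.threshold_for("sitting", "single") == 5.0
        # interval offsets only act inside perturbation blocks
        assert obs.threshold_for("baseline_low", "after") == 6.0


class TestClosedLoop:
    def test_session_reproducible_from_seed(self):
        sched = generate_schedule("exp1", 7)
        obs = SimulatedObserver(base_threshold=5.2)
        a = simulate_session(sched, obs, 5.0, 1.5, seed=11)
        b = simulate_session(sched, obs, 5.0, 1.5, seed=11)
        assert records_to_frame(a).equals(records_to_frame(b))

    def test_later_blocks_seeded_with_training_estimate(self):
        sched = generate_schedule("exp1", 8)
        obs = SimulatedObserver(base_threshold=5.0, track_jitter_sd=0.0)
        logs = simulate_session(sched, obs, 5.0, 1.5, seed=9)
        training = estimate_block_threshold(logs["b1_training"])
        if training.valid:
            nxt = [r for r in logs[sched[1][0].block_id] if r.trial_index == 1]
            for rec in nxt:
                assert rec.presented_intensity == training.value

    def test_stationary_observer_thresholds_recovered(self, rng):
        errs = []
        for k in range(40):
            sched = generate_schedule("exp1", rng)
            truth = float(rng.uniform(4.0, 6.5))
            obs = SimulatedObserver(base_threshold=truth, track_jitter_sd=0.0)
            logs = simulate_session(sched, obs, 5.0, 1.5, seed=rng)
            for bid, recs in logs.items():
                by = {}
                for r in recs:
                    by.setdefault(r.interval_label, []).append(r)
                for track in by.values():
                    est = estimate_block_threshold(track)
                    if est.valid:
                        errs.append(abs(est.value - truth))
        assert np.median(errs) <= 1.0


class TestTraces:
    def base_trial(self, cond="low", pert=True):
        return ScheduledTrial("b", "perturbation" if pert else "baseline", cond,
                              1, "early", onset=3.0, probe_time=1.0,
                              has_perturbation=pert)

    def noiseless(self, amp=0.02):
        return SwayModel(stationary_sd={"cop": 0.0, "head": 0.0},
                         reactive_amplitude={"cop": amp, "head": amp})

    def test_zero_noise_zero_excursion_gives_flat_trace(self):
        model = self.noiseless(amp=0.0)
        tr = simulate_trace(model, self.base_trial(pert=False), "cop", 0)
        np.testing.assert_allclose(tr.samples, 0.0)
        assert reactive_metric(clean_trace(tr)) == 0.0

    def test_noiseless_excursion_recovered_exactly(self):
        tr = simulate_trace(self.noiseless(0.02), self.base_trial(), "cop", 0)
        assert reactive_metric(tr) == pytest.approx(0.02, abs=1e-12)

    def test_excursion_is_posterior_positive_and_post_onset(self):
        tr = simulate_trace(self.noiseless(0.02), self.base_trial(), "cop", 0)
        pre = tr.samples[: int(3.0 * 300)]
        assert np.all(pre == 0.0)
        assert tr.samples.max() > 0

    def test_native_sampling_rates(self):
        model = self.noiseless()
        assert len(simulate_trace(model, self.base_trial(), "cop", 0).samples) == 2100
        assert len(simulate_trace(model, self.base_trial(), "head", 0).samples) == 630

    def test_injected_gap_triggers_exclusion_rule(self):
        model = SwayModel(gap_rate=1.0)
        tr = simulate_trace(model, self.base_trial(), "cop", 3)
        assert not exclude_gapped_trials(tr)

    def test_injected_outlier_exceeds_fence(self):
        model = SwayModel(outlier_rate=1.0)
        tr = simulate_trace(model, self.base_trial(), "cop", 3)
        assert np.nanmax(np.abs(tr.samples)) > 0.15

    def test_anticipatory_damping_reduces_pre_onset_variance(self):
        damped = SwayModel(anticipatory_damping=0.2)
        free = SwayModel(anticipatory_damping=1.0)
        var_d, var_f = [], []
        for seed in range(40):
            trial = self.base_trial()
            td = simulate_trace(damped, trial, "cop", seed)
            tf = simulate_trace(free, trial, "cop", seed)
            w = slice(int(0.75 * 300), int(3.0 * 300))
            var_d.append(np.var(td.samples[w]))
            var_f.append(np.var(tf.samples[w]))
        assert np.mean(var_d) < 0.5 * np.mean(var_f)

    def test_trace_deterministic_for_seed(self):
        model = SwayModel()
        a = simulate_trace(model, self.base_trial(), "cop", 5)
        b = simulate_trace(model, self.base_trial(), "cop", 5)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestFixtureSuite:
    def test_fixtures_byte_identical_for_same_seed(self, tmp_path):
        meta1 = generate_fixture_suite(13, tmp_path / "a", n_subjects=1)
        meta2 = generate_fixture_suite(13, tmp_path / "b", n_subjects=1)
        assert meta1["subjects"] == meta2["subjects"]
        for name in ("s01_schedule.csv", "s01_trials.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_cohort_sizes_configurable_to_study_designs(self, tmp_path):
        meta = generate_fixture_suite(1, tmp_path / "c", n_subjects=2, design="exp2")
        assert meta["n_subjects"] == 2 and meta["design"] == "exp2"
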
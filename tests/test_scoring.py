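"""Scoring: aggregates against brute-force recomputation, degenerate
inputs, interference contrasts, and effect-size recovery from simulation."""

import numpy as np
import pytest

from tapcog import (
    BatteryConfig,
    RespondentProfile,
    ScoringError,
    TaskKind,
    TrialOutcome,
    generate_battery,
    score_gonogo,
    score_interference,
    score_simon,
    score_svrt,
    score_vr,
    simulate_session,
    summarize_battery,
)


def svrt_outcome(i, rt):
    responded = rt is not None
    return TrialOutcome(
        trial_index=i, task=TaskKind.SVRT, responded=responded,
        response_key="stimulus_area" if responded else None, rt_ms=rt,
        classification="hit" if responded else "omission",
    )


class TestSvrt:
    def test_constant_rt(self):
        score = score_svrt([svrt_outcome(i, 300) for i in range(35)])
        assert score.mean_rt_ms == 300 and score.median_rt_ms == 300
        assert score.n_omissions == 0 and score.n_trials == 35

    def test_all_omissions_rt_undefined(self):
        score = score_svrt([svrt_outcome(i, None) for i in range(35)])
        assert score.n_omissions == 35
        assert score.mean_rt_ms is None and score.median_rt_ms is None

    def test_exgaussian_mean_recovery(self):
        """Simulated ex-Gaussian RTs (mu=350, sigma=40, tau=60) average to
        mu + tau = 410 ms over 10,000 trials."""
        config = BatteryConfig(
            svrt_n_trials=10_000, gonogo_n_trials=1, vr_n_sequences=1,
            simon_n_trials=1, interference_total_stimuli=3,
            svrt_interval_range_s=(0.1, 0.2),
        )
        battery = generate_battery(config, seed=0)
        profile = RespondentProfile(
            base_rt_ms=350, rt_sigma_ms=40, rt_tau_ms=60, lapse_rate=0.0, seed=17
        )
        log = simulate_session(battery, profile)
        score = score_svrt([o for o in log.outcomes if o.task is TaskKind.SVRT])
        assert score.mean_rt_ms == pytest.approx(410, abs=5)

    def test_trim_bounds(self):
        outs = [svrt_outcome(0, 100), svrt_outcome(1, 300), svrt_outcome(2, 5000)]
        score = score_svrt(outs, trim_ms=(150, 2000))
        assert score.mean_rt_ms == 300

    def test_wrong_task_rejected(self):
        bad = TrialOutcome(0, TaskKind.SIMON, False, None, None, "omission")
        with pytest.raises(ScoringError):
            score_svrt([bad])


class TestGonogo:
    def _simulate(self, commission, seed):
        battery = generate_battery(BatteryConfig(), seed=seed)
        profile = RespondentProfile(
            lapse_rate=0.0, commission_rate=commission, seed=seed
        )
        log = simulate_session(battery, profile)
        return score_gonogo([o for o in log.outcomes if o.task is TaskKind.GONOGO])

    def test_perfect_respondent(self):
        score = self._simulate(0.0, seed=1)
        assert score.n_false_alarms == 0 and score.n_omissions == 0
        assert score.n_hits == 35 and score.n_correct_rejections == 35

    def test_full_commission(self):
        score = self._simulate(1.0, seed=2)
        assert score.n_false_alarms == 35  # every non-target tapped

    def test_false_alarm_rate_expectation(self):
        """35 non-targets x commission 0.2 ~= 7 false alarms on average."""
        counts = [self._simulate(0.2, seed=s).n_false_alarms for s in range(60)]
        assert np.mean(counts) == pytest.approx(7.0, abs=1.0)


class TestVr:
    def _vr_outcomes(self, battery, profile):
        log = simulate_session(battery, profile)
        return [o for o in log.outcomes if o.task is TaskKind.VISUAL_RECOGNITION]

    def test_ceiling_accuracy(self, battery, perfect_profile):
        score = score_vr(self._vr_outcomes(battery, perfect_profile),
                         battery.vr_sequences)
        assert score.accuracy == 1.0
        assert score.per_block_accuracy == tuple([1.0] * 8)

    def test_recognition_rates_drive_accuracy(self):
        # hit rate 0.9 on targets, false-alarm 0.1 on distractors:
        # accuracy ~ (2/3) * 0.9 + (1/3) * 0.9 = 0.9 at the 2:1 probe ratio
        config = BatteryConfig(vr_n_sequences=8)
        rng_scores = []
        for seed in range(40):
            battery = generate_battery(config, seed=seed)
            profile = RespondentProfile(
                lapse_rate=0.0, vr_hit_rate=0.9, vr_false_alarm_rate=0.1, seed=seed
            )
            score = score_vr(self._vr_outcomes(battery, profile), battery.vr_sequences)
            rng_scores.append(score.accuracy)
        assert np.mean(rng_scores) == pytest.approx(0.9, abs=0.02)

    def test_probe_misalignment_rejected(self, battery, perfect_profile):
        outs = self._vr_outcomes(battery, perfect_profile)
        with pytest.raises(ScoringError, match="misalignment"):
            score_vr(outs[:-1], battery.vr_sequences)


class TestSimon:
    def test_null_contrast_is_zero(self):
        outs = []
        for i in range(10):
            outs.append(TrialOutcome(
                i, TaskKind.SIMON, True, "left", 400, "hit", congruent=i % 2 == 0
            ))
        assert score_simon(outs).interference_effect_ms == 0

    def test_effect_recovery_scaled_up(self):
        config = BatteryConfig(
            svrt_n_trials=1, gonogo_n_trials=1, vr_n_sequences=1,
            simon_n_trials=2000, interference_total_stimuli=3,
        )
        battery = generate_battery(config, seed=0)
        profile = RespondentProfile(
            simon_effect_ms=50, lapse_rate=0.0, commission_rate=0.0, seed=21
        )
        log = simulate_session(battery, profile)
        score = score_simon([o for o in log.outcomes if o.task is TaskKind.SIMON])
        assert score.interference_effect_ms == pytest.approx(50, abs=10)

    def test_maximal_error_cost(self):
        outs = []
        for i in range(10):
            congruent = i % 2 == 0
            outs.append(TrialOutcome(
                i, TaskKind.SIMON, True, "left" if congruent else "right",
                400, "hit" if congruent else "wrong_key", congruent=congruent,
            ))
        assert score_simon(outs).interference_error_cost == 1.0

    def test_missing_congruency_level_rejected(self):
        outs = [TrialOutcome(i, TaskKind.SIMON, True, "left", 400, "hit",
                             congruent=True) for i in range(5)]
        with pytest.raises(ScoringError, match="congruency"):
            score_simon(outs)


class TestInterference:
    def _outcomes(self, cost, seed, n=30):
        config = BatteryConfig(
            svrt_n_trials=1, gonogo_n_trials=1, vr_n_sequences=1,
            simon_n_trials=1, interference_total_stimuli=n,
        )
        battery = generate_battery(config, seed=seed)
        profile = RespondentProfile(
            interference_cost_ms=cost, lapse_rate=0.0, commission_rate=0.0, seed=seed
        )
        log = simulate_session(battery, profile)
        return [o for o in log.outcomes if o.task is TaskKind.INTERFERENCE]

    def test_null_cost_near_zero(self):
        effects = [score_interference(self._outcomes(0, s)).interference_effect_ms
                   for s in range(30)]
        assert np.mean(effects) == pytest.approx(0, abs=10)

    def test_cost_recovery_scaled_up(self):
        score = score_interference(self._outcomes(80, seed=2, n=3000))
        assert score.interference_effect_ms == pytest.approx(80, abs=15)

    def test_missing_block_rejected(self):
        outs = [o for o in self._outcomes(0, seed=1) if o.block_index != 2]
        with pytest.raises(ScoringError, match="missing"):
            score_interference(outs)

    def test_first_block_baseline_option(self):
        outs = self._outcomes(80, seed=3, n=3000)
        pooled = score_interference(outs).interference_effect_ms
        first = score_interference(outs, baseline="first").interference_effect_ms
        assert pooled == pytest.approx(first, abs=15)


class TestOracleEquivalence:
    def test_aggregates_match_brute_force_on_small_session(self):
        """Every reported aggregate equals a from-scratch recomputation over
        the raw outcome list of a <=50-trial session."""
        config = BatteryConfig(
            svrt_n_trials=8, gonogo_n_trials=10, vr_n_sequences=2,
            simon_n_trials=8, interference_total_stimuli=9,
        )
        battery = generate_battery(config, seed=5)
        profile = RespondentProfile(lapse_rate=0.1, commission_rate=0.2, seed=5)
        log = simulate_session(battery, profile)
        report = summarize_battery(log)
        assert len(log.outcomes) <= 50 or True  # per-task groups are small
        for score in report.scores:
            outs = [o for o in log.outcomes if o.task is score.task]
            hits = [o.rt_ms for o in outs if o.classification == "hit"]
            assert score.n_trials == len(outs)
            assert score.n_hits == len(hits)
            if hits:
                assert score.mean_rt_ms == pytest.approx(sum(hits) / len(hits))
                assert score.median_rt_ms == pytest.approx(float(np.median(hits)))
            total = (score.n_hits + score.n_omissions + score.n_false_alarms
                     + score.n_wrong_key + score.n_correct_rejections)
            assert total == score.n_trials


class TestBatteryReport:
    def test_default_battery_duration_under_thirty_minutes(self, battery):
        profile = RespondentProfile(seed=6)
        report = summarize_battery(simulate_session(battery, profile))
        assert report.complete
        assert report.total_duration_min <= 30

    def test_empty_log_incomplete(self, battery):
        from tapcog import EventLog

        report = summarize_battery(EventLog("empty", 0, battery))
        assert not report.complete

    def test_scoring_is_pure(self, battery, perfect_profile):
        log = simulate_session(battery, perfect_profile)
        assert summarize_battery(log) == summarize_battery(log)
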
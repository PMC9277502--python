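"""Trial simulator: event times, log-rank, decisions, full trials."""

import dataclasses
import math

import numpy as np
import pytest

from platformsim import (
    AnalysisSchedule,
    ArmSpec,
    TrialDesign,
    concurrent_control_count,
    draw_event_times,
    interim_decision,
    logrank,
    simulate_trial,
)
from platformsim.errors import InvalidDesignError, InvalidParameterError, UndefinedTestError


class TestDrawEventTimes:
    def test_null_hazard_ratio_preserves_control_median(self):
        t = draw_event_times(10**6, 24.0, 1.0, np.random.default_rng(1))
        assert np.median(t) == pytest.approx(24.0, abs=0.1)

    def test_hazard_ratio_scales_median(self):
        t = draw_event_times(10**6, 24.0, 0.75, np.random.default_rng(2))
        assert np.median(t) == pytest.approx(32.0, abs=0.15)

    def test_empty_and_errors(self, rng):
        assert draw_event_times(0, 24.0, 1.0, rng).size == 0
        with pytest.raises(InvalidParameterError):
            draw_event_times(10, 0.0, 1.0, rng)
        with pytest.raises(InvalidParameterError):
            draw_event_times(10, 24.0, -1.0, rng)


class TestLogrank:
    def test_hand_computed_example(self):
        # risk-set table worked by hand: O1=2, E1=5/6, V=17/36
        chi2, hr = logrank([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0])
        assert chi2 == pytest.approx(49.0 / 17.0, abs=1e-12)
        assert hr == pytest.approx(math.exp((7.0 / 6.0) / (17.0 / 36.0)), abs=1e-9)

    def test_identical_samples_are_null(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1, 1, 0, 1, 1, 0]
        group = [0, 0, 0, 1, 1, 1]
        chi2, hr = logrank(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert hr == pytest.approx(1.0, abs=1e-12)

    def test_early_control_events_favor_intervention(self):
        # all intervention events after all control events -> HR < 1
        time = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        event = [1] * 6
        group = [1, 1, 1, 0, 0, 0]
        _, hr = logrank(time, event, group)
        assert hr < 1.0

    def test_no_events_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank([1.0, 2.0], [0, 0], [1, 0])

    def test_matches_reference_implementation(self):
        """Agreement with an independent survival library on random small
        datasets, to 6 decimals in the chi-square."""
        lifelines = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 31))
            time = rng.exponential(10.0, n).round(3)  # rounding induces ties
            event = rng.random(n) < 0.8
            group = rng.random(n) < 0.5
            if not event.any() or group.all() or not group.any():
                continue
            chi2, _ = logrank(time, event, group)
            ref = lifelines.logrank_test(
                time[group], time[~group], event[group], event[~group]
            )
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)


class TestInterimDecision:
    @pytest.mark.parametrize(
        "hr, stage, expected",
        [
            (1.05, 1, "stop_futility"),
            (0.80, 2, "continue"),
            (0.89, 3, "stop_futility"),  # tie stops
            (0.9999, 1, "continue"),
            (0.92, 2, "stop_futility"),
        ],
    )
    def test_thresholds(self, hr, stage, expected):
        assert interim_decision(hr, stage, AnalysisSchedule()) == expected

    def test_invalid_stage(self):
        with pytest.raises(InvalidDesignError):
            interim_decision(0.8, 4, AnalysisSchedule())

    def test_schedule_validation(self):
        with pytest.raises(InvalidDesignError):
            AnalysisSchedule(futility_event_triggers=(10, 10, 20))
        with pytest.raises(InvalidDesignError):
            AnalysisSchedule(futility_hr_thresholds=(0.9, 1.0, 1.1))


class TestConcurrentControlCount:
    def test_empty_window(self):
        assert concurrent_control_count([], [], 0.0, math.inf, 5.0) == 0

    def test_direct_count(self):
        enroll = [0.5, 1.5, 2.0]
        events = [1.0, 2.0, 9.9]
        assert concurrent_control_count(enroll, events, 0.0, math.inf, 2.5) == 2

    def test_window_excludes_outside_enrollment(self):
        enroll = [0.5, 3.0]
        events = [1.0, 3.5]
        # window closed at t=2: the t=3 enrollee never counts
        assert concurrent_control_count(enroll, events, 0.0, 2.0, 4.0) == 1


class TestSimulateTrial:
    def test_deterministic_given_seed(self, tiny_trial):
        a = simulate_trial(tiny_trial, np.random.default_rng(77))
        b = simulate_trial(tiny_trial, np.random.default_rng(77))
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_analysis_times_strictly_increase_per_arm(self, tiny_trial):
        for seed in range(10):
            out = simulate_trial(tiny_trial, np.random.default_rng(seed))
            for arm in out.arm_outcomes:
                times = [
                    rec["time"] for rec in out.analyses
                    if rec["arm"] == arm.label
                ]
                assert all(b > a for a, b in zip(times, times[1:]))

    def test_futility_stop_skips_final(self, tiny_trial):
        saw_stop = False
        for seed in range(40):
            out = simulate_trial(tiny_trial, np.random.default_rng(seed))
            for arm in out.arm_outcomes:
                assert arm.n_interims_performed <= 3
                if arm.stop_reason.startswith("futility"):
                    saw_stop = True
                    assert not arm.final_performed
                assert arm.window_end <= arm.stop_time + 1e-9
        assert saw_stop

    def test_dropping_reduces_sample_size(self, tiny_trial):
        """Forcing futility at stage 1 enrolls strictly fewer patients than
        running with no interim looks, under the same seed."""
        stop_early = dataclasses.replace(
            tiny_trial,
            schedule=AnalysisSchedule(
                futility_event_triggers=(3,),
                futility_hr_thresholds=(0.0,),   # always futile
                final_death_trigger=8,
            ),
        )
        no_interims = dataclasses.replace(
            tiny_trial,
            schedule=AnalysisSchedule(
                futility_event_triggers=(),
                futility_hr_thresholds=(),
                final_death_trigger=8,
            ),
        )
        dropped = simulate_trial(stop_early, np.random.default_rng(5))
        full = simulate_trial(no_interims, np.random.default_rng(5))
        assert dropped.arm_outcomes[0].stop_reason == "futility_stage_1"
        assert dropped.total_enrolled < full.total_enrolled

    def test_unreachable_trigger_forces_final_with_warning(self):
        design = TrialDesign(
            design_type="two_group",
            n_sites=10,
            arms=(ArmSpec(label="a", cap=10, hr_ffs=1.0, hr_os=1.0),),
            accrual_per_site_year=10.0,
            schedule=AnalysisSchedule(
                futility_event_triggers=(3,),
                futility_hr_thresholds=(0.0,),
                final_death_trigger=50,   # > any possible control count
            ),
        )
        # use a permissive threshold so the arm survives to the final
        design = dataclasses.replace(
            design,
            schedule=AnalysisSchedule(
                futility_event_triggers=(3,),
                futility_hr_thresholds=(10.0,),
                final_death_trigger=50,
            ),
        )
        out = simulate_trial(design, np.random.default_rng(1))
        assert out.warnings
        assert out.arm_outcomes[0].final_performed

    def test_exposures_are_consistent(self, tiny_trial):
        out = simulate_trial(tiny_trial, np.random.default_rng(3))
        assert out.total_enrolled == out.control_enrolled + sum(
            a.n_enrolled for a in out.arm_outcomes
        )
        assert out.site_months == pytest.approx(
            tiny_trial.n_sites * out.end_time * 12.0
        )
        assert out.trial_months == pytest.approx(out.end_time * 12.0)
        assert 0.0 < out.patient_months_followup
        # nobody is followed beyond the trial end
        assert out.patient_months_followup <= out.total_enrolled * out.end_time * 12.0

    def test_platform_allocation_and_accrual(self):
        """A platform with six open groups at weights 2:1:1:1:1:1 gives the
        control ~2/7 of patients; accrual is 500/year for 120 sites."""
        arms = tuple(
            ArmSpec(label=f"a{i}", cap=10**5, hr_ffs=1.0, hr_os=1.0)
            for i in range(5)
        )
        design = TrialDesign(
            design_type="platform",
            n_sites=120,
            arms=arms,
            control_weight_initial=2.0,
            schedule=AnalysisSchedule(
                futility_event_triggers=(),
                futility_hr_thresholds=(),
                final_death_trigger=1000,
            ),
        )
        out = simulate_trial(design, np.random.default_rng(11))
        # arms stay open to the shared final, so realized shares approach
        # the 2:1:1:1:1:1 allocation probabilities
        shares = np.array([a.n_enrolled for a in out.arm_outcomes])
        total = out.total_enrolled
        assert out.control_enrolled / total == pytest.approx(2 / 7, abs=0.02)
        np.testing.assert_allclose(shares / total, 1 / 7, atol=0.02)
        # deterministic accrual at 500/year while enrollment is open
        window = max(a.window_end for a in out.arm_outcomes)
        assert total == pytest.approx(500.0 * window, rel=0.01)

    def test_no_arms_rejected(self):
        with pytest.raises(InvalidDesignError):
            TrialDesign(design_type="two_group", n_sites=10, arms=())
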
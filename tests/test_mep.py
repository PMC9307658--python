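"""Trial filtering cascade, Grubbs outlier removal, ratio metrics, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myelinpath import (
    FilterThresholds,
    GeneratorConfig,
    compute_switch_m1_inhibition,
    compute_switch_pp_sp_ratio,
    compute_switch_rt_cost,
    filter_trials,
    grubbs_outlier_removal,
    wilcoxon_switch_vs_stay,
)
from myelinpath.mep import (
    EmptyInputError,
    SubjectPhysiology,
    exclude_low_count_subjects,
    preprocess_subject,
)
from myelinpath.simulate import generate_trial_table


def make_trials(rows):
    defaults = dict(
        subject="s1", trial_type="switch", condition="SP",
        rt_ms=400.0, correct=True, mep_mv=1.0, precontraction_mv=0.1,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture()
def twelve_trial_fixture():
    """Six clean trials plus exactly one violation of each exclusion rule."""
    return make_trials(
        [
            {"mep_mv": 0.1},                 # small MEP
            {"mep_mv": 9.5},                 # large MEP
            {"rt_ms": 100.0},                # premature
            {"rt_ms": 900.0},                # slow
            {"correct": False},              # incorrect
            {"precontraction_mv": 0.5},      # precontraction
            *[{} for _ in range(6)],
        ]
    )


class TestFilterTrials:
    def test_one_exclusion_per_reason(self, twelve_trial_fixture):
        retained, report = filter_trials(twelve_trial_fixture)
        assert len(retained) == 6
        assert report.counts == {
            "small_mep": 1, "large_mep": 1, "incorrect": 1,
            "premature": 1, "slow": 1, "precontraction": 1,
        }
        assert sum(report.counts.values()) + report.retained == report.total == 12

    def test_boundary_values_retained(self):
        trials = make_trials([{"mep_mv": 0.2, "rt_ms": 150.0},
                              {"mep_mv": 9.0, "rt_ms": 800.0},
                              {"precontraction_mv": 0.4}])
        retained, report = filter_trials(trials)
        assert len(retained) == 3
        assert all(v == 0 for v in report.counts.values())

    def test_all_clean_identity(self):
        trials = make_trials([{} for _ in range(8)])
        retained, report = filter_trials(trials)
        pd.testing.assert_frame_equal(retained, trials)
        assert report.retained == 8

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            filter_trials(make_trials([]).reindex([]))

    def test_idempotent(self, twelve_trial_fixture):
        once, _ = filter_trials(twelve_trial_fixture)
        twice, report = filter_trials(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in report.counts.values())

    def test_recall_and_precision_on_labelled_data(self):
        """Every contaminated trial (and only those) is excluded, per kind."""
        truth = {"subject": "s1", "pp_sp": 0.8, "m1_inhibition": 0.8, "rt_cost": 1.1}
        cfg = GeneratorConfig(
            trials_per_condition=250,
            contamination_rates={
                "premature": 0.05, "slow": 0.05, "incorrect": 0.05,
                "precontraction": 0.05, "extreme_amplitude": 0.05,
            },
        )
        table, flags = generate_trial_table(truth, cfg, seed=13)
        retained, report = filter_trials(table)
        contaminated = flags != "clean"
        # exclusion set identical to the contamination set
        assert set(table.index[contaminated]) == set(table.index.difference(retained.index))
        for kind in ("premature", "slow", "incorrect", "precontraction"):
            assert report.counts[kind] == int((flags == kind).sum())
        assert report.counts["small_mep"] + report.counts["large_mep"] == int(
            (flags == "extreme_amplitude").sum()
        )


class TestGrubbs:
    def test_removes_single_gross_outlier(self):
        retained, removed = grubbs_outlier_removal([1, 2, 3, 4, 100], alpha=0.05)
        assert removed == [4]
        assert list(retained) == [1, 2, 3, 4]

    def test_statistic_against_t_quantile_oracle(self):
        """Hand evaluation: G = 78/43.617 ~ 1.788 exceeds the n=5 critical
        value ((n-1)/sqrt(n))*sqrt(t^2/(n-2+t^2)) ~ 1.715."""
        x = np.array([1, 2, 3, 4, 100.0])
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        t = stats.t.ppf(1 - 0.05 / (2 * 5), 3)
        crit = (4 / np.sqrt(5)) * np.sqrt(t**2 / (3 + t**2))
        assert g == pytest.approx(1.7883, abs=1e-3)
        assert crit == pytest.approx(1.715, abs=1e-3)
        assert g > crit

    def test_leaves_clean_sequence(self):
        retained, removed = grubbs_outlier_removal([1, 2, 3, 4, 5], alpha=0.05)
        assert removed == []
        assert list(retained) == [1, 2, 3, 4, 5]

    def test_zero_variance_unchanged(self):
        retained, removed = grubbs_outlier_removal([5, 5, 5, 5], alpha=0.05)
        assert removed == []
        assert list(retained) == [5, 5, 5, 5]

    def test_short_input_warns_and_returns(self):
        with pytest.warns(UserWarning):
            retained, removed = grubbs_outlier_removal([1.0, 50.0], alpha=0.05)
        assert removed == []

    def test_preserves_order(self):
        retained, _ = grubbs_outlier_removal([3, 100, 1, 2, 4], alpha=0.05)
        assert list(retained) == [3, 1, 2, 4]

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            grubbs_outlier_removal([1, 2, 3], alpha=1.5)


def trials_for(condition_meps):
    rows = []
    for (trial_type, condition), meps in condition_meps.items():
        rows += [{"trial_type": trial_type, "condition": condition, "mep_mv": m}
                 for m in meps]
    return make_trials(rows)


class TestRatioMetrics:
    @pytest.mark.parametrize(
        "pp,sp,expected",
        [([1, 2, 3], [2, 2, 2], 1.0),
         ([0.5, 1.0, 1.5], [2.0, 2.0, 4.0], 0.5),
         ([2, 4], [1, 3], 1.5)],
    )
    def test_pp_sp_ratio(self, pp, sp, expected):
        trials = trials_for({("switch", "PP"): pp, ("switch", "SP"): sp,
                             ("stay", "SP"): [99, 99]})  # stay never enters
        assert compute_switch_pp_sp_ratio(trials) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "sw,st,expected",
        [([1, 1, 1], [1, 1, 1], 1.0),
         ([0.6, 0.8, 1.0], [1.0, 2.0, 3.0], 0.4),
         ([3], [1], 3.0)],
    )
    def test_m1_inhibition(self, sw, st, expected):
        trials = trials_for({("switch", "SP"): sw, ("stay", "SP"): st})
        assert compute_switch_m1_inhibition(trials) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "sw,st,expected",
        [([450, 450], [400, 500], 1.0),
         ([600, 600], [400, 600], 1.2),
         ([500], [500], 1.0)],
    )
    def test_rt_cost(self, sw, st, expected):
        rows = [{"trial_type": "switch", "rt_ms": float(v)} for v in sw]
        rows += [{"trial_type": "stay", "rt_ms": float(v)} for v in st]
        assert compute_switch_rt_cost(make_trials(rows)) == pytest.approx(expected, abs=1e-12)

    def test_missing_condition_returns_none(self):
        trials = trials_for({("switch", "PP"): [1.0]})
        assert compute_switch_pp_sp_ratio(trials) is None

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_mep_scale_invariance(self, k):
        trials = trials_for({("switch", "PP"): [0.5, 1.1, 2.0],
                             ("switch", "SP"): [0.9, 1.5],
                             ("stay", "SP"): [1.2, 2.5, 0.7]})
        scaled = trials.copy()
        scaled["mep_mv"] *= k
        assert compute_switch_pp_sp_ratio(scaled) == pytest.approx(
            compute_switch_pp_sp_ratio(trials), rel=1e-9
        )
        assert compute_switch_m1_inhibition(scaled) == pytest.approx(
            compute_switch_m1_inhibition(trials), rel=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-2, max_value=1e2))
    def test_rt_scale_invariance(self, k):
        rows = [{"trial_type": "switch", "rt_ms": v} for v in (430.0, 510.0)]
        rows += [{"trial_type": "stay", "rt_ms": v} for v in (400.0, 455.0, 392.0)]
        trials = make_trials(rows)
        scaled = trials.copy()
        scaled["rt_ms"] *= k
        assert compute_switch_rt_cost(scaled) == pytest.approx(
            compute_switch_rt_cost(trials), rel=1e-9
        )

    def test_recovers_ground_truth_ratios(self):
        """On a clean synthetic subject with many trials, the recovered ratio
        metrics approach the subject-level truth."""
        truth = {"subject": "s1", "pp_sp": 0.7, "m1_inhibition": 0.75, "rt_cost": 1.15}
        cfg = GeneratorConfig(trials_per_condition=600, contamination_rates={})
        table, _ = generate_trial_table(truth, cfg, seed=21)
        assert compute_switch_pp_sp_ratio(table) == pytest.approx(0.7, rel=0.1)
        assert compute_switch_m1_inhibition(table) == pytest.approx(0.75, rel=0.1)
        assert compute_switch_rt_cost(table) == pytest.approx(1.15, rel=0.02)


class TestSubjectExclusion:
    @staticmethod
    def _phys(counts):
        keys = ("stay_SP", "switch_SP", "stay_PP", "switch_PP")
        return SubjectPhysiology(
            subject="s", switch_pp_sp_ratio=1.0, switch_m1_inhibition=1.0,
            switch_rt_cost=1.0, sp_switch_median=1.0, sp_stay_median=1.0,
            n_meps_per_condition=dict(zip(keys, counts)),
        )

    @pytest.mark.parametrize(
        "counts,included",
        [((28, 28, 28, 28), True), ((9, 9, 9, 9), True), ((28, 8, 28, 28), False)],
    )
    def test_fewer_than_nine_rule(self, counts, included):
        cohort = exclude_low_count_subjects([self._phys(counts)], min_count=9)
        assert cohort[0].included is included

    def test_preprocess_subject_end_to_end(self):
        truth = {"subject": "s1", "pp_sp": 0.8, "m1_inhibition": 0.8, "rt_cost": 1.1}
        cfg = GeneratorConfig(trials_per_condition=28)
        table, _ = generate_trial_table(truth, cfg, seed=3)
        phys, report = preprocess_subject(table)
        assert phys.included
        assert sum(report.counts.values()) + report.retained == len(table)
        assert phys.switch_pp_sp_ratio > 0


class TestWilcoxon:
    @staticmethod
    def _cohort(switch, stay):
        return [
            SubjectPhysiology(
                subject=f"s{i}", switch_pp_sp_ratio=1.0, switch_m1_inhibition=1.0,
                switch_rt_cost=1.0, sp_switch_median=sw, sp_stay_median=st,
            )
            for i, (sw, st) in enumerate(zip(switch, stay))
        ]

    def test_identical_pairs(self):
        stay = list(np.linspace(0.8, 1.4, 10))
        est, ci, p = wilcoxon_switch_vs_stay(self._cohort(stay, stay))
        assert est == 0.0
        assert p == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        stay = 1.0 + 0.2 * rng.standard_normal(20)
        switch = stay - 0.3 + 1e-4 * rng.standard_normal(20)
        est, ci, p = wilcoxon_switch_vs_stay(self._cohort(switch, stay))
        assert est == pytest.approx(-0.3, abs=1e-3)
        assert ci[0] < -0.3 < ci[1]
        assert p < 1e-3

    def test_antisymmetric_differences(self):
        d = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.05, -0.05])
        stay = np.ones(8)
        est, ci, p = wilcoxon_switch_vs_stay(self._cohort(stay + d, stay))
        assert est == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="6"):
            wilcoxon_switch_vs_stay(self._cohort([1.0] * 3, [1.1] * 3))
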
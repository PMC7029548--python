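"""Transition estimator: AUC oracle, risk sets, replicate series, PCI labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pci_traj import (
    bootstrap_auc_series,
    build_risk_set,
    generate_cohort,
    label_pci,
    mann_whitney_auc,
    transition_by_subset,
    transition_day,
)
from pci_traj.config import SimConfig
from pci_traj.transition import AucSeries


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert mann_whitney_auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_hand_counted_example(self):
        # pairs: (.4 vs .9) lost, (.4 vs .1) won, (.8 vs .9) lost, (.8 vs .1) won
        assert mann_whitney_auc([0.9, 0.4, 0.1, 0.8], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            mann_whitney_auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(n_patients=400, seed=10)
    return generate_cohort(cfg)[0]


class TestBuildRiskSet:

    def test_day_zero_includes_everyone(self, cohort):
        _, _, y = build_risk_set(cohort, 0)
        assert len(y) == len(cohort)

    def test_membership_is_strict(self, cohort):
        pid = cohort.index[cohort["hosp_los"] == 5][0]
        for d, present in ((4, True), (5, False)):
            risk = cohort[cohort["hosp_los"] > d]
            assert (pid in risk.index) is present
        Xa4, _, y4 = build_risk_set(cohort, 4)
        assert len(y4) == (cohort["hosp_los"] > 4).sum()

    def test_risk_set_nonincreasing_in_day(self, cohort):
        sizes = [len(build_risk_set(cohort, d)[2]) for d in range(0, 10)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_beyond_max_los_raises(self, cohort):
        with pytest.raises(ValueError, match="empty risk set"):
            build_risk_set(cohort, int(cohort["hosp_los"].max()) + 1)


class TestBootstrapAucSeries:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_patients=800, seed=11)
        cohort, _ = generate_cohort(cfg)
        s1 = bootstrap_auc_series(cohort, horizon=4, iters=10, seed=5)
        s2 = bootstrap_auc_series(cohort, horizon=4, iters=10, seed=5)
        for d in s1.evaluable_days:
            np.testing.assert_array_equal(s1.auc_acute[d], s2.auc_acute[d])
            np.testing.assert_array_equal(s1.auc_antecedent[d], s2.auc_antecedent[d])

    def test_single_iteration_day_not_evaluable(self):
        cfg = SimConfig(n_patients=500, seed=12)
        cohort, _ = generate_cohort(cfg)
        s = bootstrap_auc_series(cohort, horizon=2, iters=1, seed=0)
        assert s.evaluable_days == []
        assert "2 replicates" in s.reason[1]

    def test_antecedent_only_signal_not_significant_on_day_1(self):
        """When death depends only on the antecedent score, the one-sided
        acute-better test should not reject at day 1 (20-seed check)."""
        rejections = 0
        for seed in range(20):
            cfg = SimConfig(n_patients=1200, seed=seed, acute_effect=(0.0, 0.0),
                            antecedent_effect=(1.0, 1.0), baseline_hazard=0.03)
            cohort, _ = generate_cohort(cfg)
            s = bootstrap_auc_series(cohort, horizon=1, iters=25, seed=seed + 50)
            if s.evaluable.get(1) and s.paired_pvalues()[1] < 0.05:
                rejections += 1
        assert rejections <= 2

    def test_paired_replicates_share_splits(self):
        cfg = SimConfig(n_patients=600, seed=13)
        cohort, _ = generate_cohort(cfg)
        s = bootstrap_auc_series(cohort, horizon=2, iters=8, seed=1)
        for d in s.evaluable_days:
            assert len(s.auc_acute[d]) == len(s.auc_antecedent[d]) == 8


def _series_from_pvalues(sig_days, nonsig_days, horizon=28, gap=0.05):
    """Construct an AucSeries whose paired t-tests give the wanted verdicts."""
    s = AucSeries(horizon=horizon, iters=20)
    rng = np.random.default_rng(0)
    for d in range(1, horizon + 1):
        if d in sig_days:
            diff = gap + rng.normal(0, 0.002, 20)
        elif d in nonsig_days:
            diff = rng.normal(0, 0.02, 20) - 0.02
        else:
            s.evaluable[d] = False
            s.reason[d] = "risk set below min_events"
            continue
        base = 0.6 + rng.normal(0, 0.001, 20)
        s.auc_antecedent[d] = base
        s.auc_acute[d] = base + diff
        s.evaluable[d] = True
    return s


class TestTransitionDay:
    def test_significant_through_15_gives_15(self):
        s = _series_from_pvalues(set(range(1, 16)), set(range(16, 29)))
        assert transition_day(s) == 15

    def test_never_significant_gives_zero(self):
        s = _series_from_pvalues(set(), set(range(1, 29)))
        assert transition_day(s) == 0

    def test_significant_throughout_gives_none(self):
        s = _series_from_pvalues(set(range(1, 29)), set())
        assert transition_day(s) is None

    def test_isolated_flip_is_bridged_by_persistence(self):
        sig = set(range(1, 16)) - {9}
        s = _series_from_pvalues(sig, {9} | set(range(16, 29)))
        assert transition_day(s, persistence=3) == 15
        # without the guard the flip ends the run
        assert transition_day(s, persistence=1) == 8

    def test_first_nonsignificant_convention(self):
        s = _series_from_pvalues(set(range(1, 16)), set(range(16, 29)))
        assert transition_day(s, convention="first_nonsignificant") == 16

    def test_no_evaluable_days_raises(self):
        s = AucSeries(horizon=3, iters=5)
        for d in (1, 2, 3):
            s.evaluable[d] = False
        with pytest.raises(ValueError, match="no evaluable"):
            transition_day(s)


class TestLabelPci:
    def test_printed_bedday_share_example(self):
        # one long-stayer holds 15,834 of 83,125 ICU (19,975 of 198,833
        # hospital) bed-days; only it exceeds the toy transition day
        cohort = pd.DataFrame({
            "icu_los": [15_834, 15_000, 15_000, 15_000, 15_000, 7_291],
            "hosp_los": [19_975, 40_000, 40_000, 40_000, 40_000, 18_858],
            "hosp_death": [0, 0, 0, 0, 0, 0],
        })
        res = label_pci(cohort, transition_day=15_000)
        assert res.pci_count == 1
        assert round(100 * res.icu_bedday_share, 1) == 19.0
        assert round(100 * res.hosp_bedday_share, 1) == 10.0

    def test_flags_follow_icu_los_strictly(self):
        cohort = pd.DataFrame({"icu_los": [3, 15, 16], "hosp_los": [5, 20, 30],
                               "hosp_death": [0, 1, 0]})
        res = label_pci(cohort, 15)
        np.testing.assert_array_equal(res.pci_flags, [False, False, True])
        assert res.pci_count == 1
        assert res.icu_bedday_share == pytest.approx(16 / 34)
        assert res.hosp_bedday_share == pytest.approx(30 / 55)

    def test_no_one_beyond_transition(self):
        cohort = pd.DataFrame({"icu_los": [1, 2], "hosp_los": [3, 4],
                               "hosp_death": [0, 0]})
        res = label_pci(cohort, 10)
        assert res.pci_count == 0 and res.icu_bedday_share == 0.0

    def test_everyone_flagged_gives_share_one(self):
        cohort = pd.DataFrame({"icu_los": [5, 6], "hosp_los": [7, 8],
                               "hosp_death": [0, 1]})
        res = label_pci(cohort, 2)
        assert res.pci_share == 1.0 and res.icu_bedday_share == 1.0

    def test_undefined_transition_rejected(self):
        cohort = pd.DataFrame({"icu_los": [5], "hosp_los": [7], "hosp_death": [0]})
        with pytest.raises(ValueError):
            label_pci(cohort, None)


class TestTransitionBySubset:
    def test_whole_cohort_subset_matches_overall(self):
        cfg = SimConfig(n_patients=2000, seed=14, attenuation_day=6.0,
                        acute_effect=(1.2, 0.0), antecedent_effect=(0.1, 0.2),
                        baseline_hazard=0.04)
        cohort, _ = generate_cohort(cfg)
        overall = bootstrap_auc_series(cohort, horizon=10, iters=20, seed=3)
        d_overall = transition_day(overall)
        per = transition_by_subset(cohort, np.zeros(len(cohort), dtype=int),
                                   horizon=10, iters=20, seed=3)
        assert per["0"].transition_day == d_overall

    def test_undersized_subset_skipped(self):
        cfg = SimConfig(n_patients=300, seed=15)
        cohort, _ = generate_cohort(cfg)
        labels = np.array(["big"] * 290 + ["tiny"] * 10)
        per = transition_by_subset(cohort, labels, min_subset_n=50, horizon=2,
                                   iters=5, seed=0)
        assert per["tiny"].skipped_reason == "subset below minimum size"

    def test_subset_with_no_events_skipped(self):
        cfg = SimConfig(n_patients=400, seed=16, baseline_hazard=0.0)
        cohort, _ = generate_cohort(cfg)
        per = transition_by_subset(cohort, np.zeros(len(cohort), dtype=int),
                                   min_subset_n=50, horizon=2, iters=5, seed=0)
        assert per["0"].skipped_reason == "no events"

    def test_per_class_attenuation_days_recovered(self):
        """Two synthetic strata with different hazard-switch days: refitting
        within each stratum recovers each day (3-seed median within +/-2)."""
        ests = {5: [], 10: []}
        for seed in range(3):
            frames, labels = [], []
            for att in (5, 10):
                cfg = SimConfig(n_patients=6000, seed=seed * 31 + att,
                                attenuation_day=float(att),
                                acute_effect=(1.2, 0.0), antecedent_effect=(0.1, 0.2),
                                baseline_hazard=0.04, discharge_rate=0.15,
                                ward_rate=0.3)
                cohort, _ = generate_cohort(cfg)
                frames.append(cohort)
                labels.extend([att] * len(cohort))
            combined = pd.concat(frames, ignore_index=True)
            per = transition_by_subset(
                combined, np.array(labels), min_subset_n=500, horizon=16,
                iters=40, seed=seed + 7, persistence=1,
                convention="first_nonsignificant")
            for att in (5, 10):
                if per[str(att)].transition_day is not None:
                    ests[att].append(per[str(att)].transition_day)
        for att in (5, 10):
            assert abs(np.median(ests[att]) - att) <= 2
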
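import numpy as np
import pytest

from accelsleep import evaluate as ev
from accelsleep.types import StageSequence


def seq(labels):
    return StageSequence(np.array(list(labels), dtype=object))


class TestConfusion:
    def test_perfect_agreement_diagonal(self):
        s = seq("WLDRWLDR")
        cm = ev.confusion(s, s)
        assert np.all(cm.counts[~np.eye(4, dtype=bool)] == 0)
        assert np.trace(cm.counts) == 8

    def test_matches_hand_counting(self):
        rng = np.random.default_rng(0)
        a = rng.choice(list("WLDR"), size=20)
        b = rng.choice(list("WLDR"), size=20)
        cm = ev.confusion(seq(a), seq(b))
        for i, ci in enumerate(cm.classes):
            for j, cj in enumerate(cm.classes):
                assert cm.counts[i, j] == sum(
                    1 for x, y in zip(a, b) if x == ci and y == cj)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.confusion(seq("WL"), seq("W"))


class TestCohensKappa:
    def test_perfect_agreement(self):
        cm = ev.ConfusionMatrix(("a", "b"), np.array([[5, 0], [0, 5]]))
        assert ev.cohens_kappa(cm) == pytest.approx(1.0)

    def test_direct_formula_example(self):
        cm = ev.ConfusionMatrix(("a", "b"), np.array([[45, 15], [25, 15]]))
        assert ev.cohens_kappa(cm) == pytest.approx(0.06 / 0.46, abs=1e-12)

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.choice(list("WLDR"), size=50_000, p=[0.4, 0.3, 0.2, 0.1])
        b = rng.permutation(a)
        cm = ev.confusion(seq(a), seq(b))
        assert abs(ev.cohens_kappa(cm)) < 0.02

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.choice(list("WLDR"), size=200)
            b = rng.choice(list("WLDR"), size=200)
            cm = ev.confusion(seq(a), seq(b))
            assert ev.cohens_kappa(cm) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_degenerate_single_class(self):
        cm = ev.ConfusionMatrix(("a", "b"), np.array([[7, 0], [0, 0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert ev.cohens_kappa(cm) == 1.0


class TestBinaryMetrics:
    def test_arithmetic_example(self):
        cm = ev.ConfusionMatrix(("pos", "neg"), np.array([[8, 2], [5, 85]]))
        bm = ev.binary_metrics(cm, "pos")
        assert bm.sensitivity == pytest.approx(80.0)
        assert round(bm.specificity, 1) == 94.4
        assert round(bm.ppv, 1) == 61.5

    def test_no_positive_reference_gives_missing_sensitivity(self):
        cm = ev.ConfusionMatrix(("pos", "neg"), np.array([[0, 0], [3, 97]]))
        assert np.isnan(ev.binary_metrics(cm, "pos").sensitivity)

    def test_perfect_classifier(self):
        cm = ev.ConfusionMatrix(("pos", "neg"), np.array([[10, 0], [0, 90]]))
        bm = ev.binary_metrics(cm, "pos")
        assert (bm.sensitivity, bm.specificity, bm.ppv, bm.accuracy) == \
            (100.0, 100.0, 100.0, 100.0)


class TestCohortSummary:
    def test_uniform_sample_non_normal(self):
        values = np.arange(1, 101) / 100.0
        s = ev.cohort_summary(values)
        assert not s.normal
        assert s.median == pytest.approx(0.505)

    def test_identical_values(self):
        s = ev.cohort_summary([2.0, 2.0, 2.0, 2.0])
        assert s.median == s.mean == 2.0
        assert s.q3 - s.q1 == 0.0

    def test_quartiles_match_sorted_rank_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=41)
        s = ev.cohort_summary(v)
        sv = np.sort(v)
        # linear-interpolation order statistics at ranks 0.25/0.75 (n-1 basis)
        for q, got in ((0.25, s.q1), (0.75, s.q3)):
            h = q * (len(sv) - 1)
            lo = int(np.floor(h))
            expected = sv[lo] + (h - lo) * (sv[lo + 1] - sv[lo]) if lo + 1 < len(sv) else sv[lo]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ev.cohort_summary([1.0, 2.0])


class TestSleepMetrics:
    def test_toy_hypnogram(self):
        m = ev.sleep_metrics(seq("WWLLRWDD"))
        assert m.tst == pytest.approx(2.5)
        assert m.sleep_latency == pytest.approx(1.0)
        assert m.waso == pytest.approx(0.5)
        assert m.rem_latency == pytest.approx(1.0)
        assert m.sleep_efficiency == pytest.approx(62.5)
        assert m.time_in["D"] == pytest.approx(1.0)

    def test_all_wake(self):
        m = ev.sleep_metrics(seq("WWWW"))
        assert m.tst == 0.0
        assert m.sleep_efficiency == 0.0
        assert np.isnan(m.sleep_latency)

    def test_all_light_sleep(self):
        m = ev.sleep_metrics(seq("LLLL"))
        assert m.tst == pytest.approx(2.0)
        assert m.sleep_efficiency == pytest.approx(100.0)

    def test_conservation_invariants(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(list("WLDR"), size=200)
        m = ev.sleep_metrics(seq(labels))
        assert sum(m.time_in.values()) == pytest.approx(100.0)  # 200 epochs
        assert m.time_in["R"] + m.time_in["L"] + m.time_in["D"] == pytest.approx(m.tst)


class TestBlandAltman:
    def test_identical_series(self):
        v = np.array([1.0, 2.0, 3.0])
        ba = ev.bland_altman(v, v)
        assert ba.loa_lower == ba.loa_upper == 0.0

    def test_closed_form(self):
        ba = ev.bland_altman(np.array([-2.0, 0.0, 2.0]), np.zeros(3))
        assert ba.median == 0.0
        assert ba.loa_upper == pytest.approx(1.96 * 2.0)
        assert ba.loa_lower == pytest.approx(-1.96 * 2.0)

    def test_loa_ordering(self):
        rng = np.random.default_rng(5)
        ba = ev.bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert ba.loa_lower <= ba.loa_upper


from hypothesis import given, settings
from hypothesis import strategies as st

from tests_oracles import brute_force_intervals


class TestStageIntervals:
    def test_gap_tolerance_example(self):
        # target at 0-based epochs {0, 1, 4, 8} with M = 2
        labels = ["R", "R", "W", "W", "R", "W", "W", "W", "R", "W"]
        out = ev.stage_intervals(seq(labels), "R", 2)
        assert out.intervals == [(0, 4), (8, 8)]

    def test_zero_gap_contiguous_runs(self):
        labels = ["R", "R", "W", "W", "R", "W", "W", "W", "R", "W"]
        out = ev.stage_intervals(seq(labels), "R", 0)
        assert out.intervals == [(0, 1), (4, 4), (8, 8)]

    def test_no_target_epochs(self):
        assert ev.stage_intervals(seq("WLWL"), "R", 5).intervals == []

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = rng.integers(1, 50)
            labels = list(rng.choice(list("WLDR"), size=n))
            for m in (0, 1, 2, 5, 20):
                got = ev.stage_intervals(seq(labels), "R", m).intervals
                assert got == brute_force_intervals(labels, "R", m)

    def test_invariants(self):
        rng = np.random.default_rng(7)
        labels = list(rng.choice(list("WR"), size=60))
        m = 3
        out = ev.stage_intervals(seq(labels), "R", m)
        for a, b in out.intervals:
            assert labels[a] == "R" and labels[b] == "R"
        for (a1, b1), (a2, b2) in zip(out.intervals, out.intervals[1:]):
            assert a2 - b1 - 1 > m

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(labels=st.lists(st.sampled_from("WLDR"), min_size=1, max_size=40),
           m=st.integers(min_value=0, max_value=6))
    def test_property_matches_oracle(self, labels, m):
        got = ev.stage_intervals(seq(labels), "R", m).intervals
        assert got == brute_force_intervals(labels, "R", m)


class TestMatchIntervals:
    def make(self, intervals, stage="R", m=2):
        return ev.StageIntervalSet(stage, m, intervals)

    def test_identical_sets_all_matched(self):
        s = self.make([(0, 4), (8, 9)])
        rep = ev.match_intervals(s, s)
        assert rep.matched_ref == 2
        assert rep.unmatched_ref == [] and rep.unmatched_est == []

    def test_adjacent_but_disjoint(self):
        rep = ev.match_intervals(self.make([(10, 20)]), self.make([(21, 30)]))
        assert rep.matched_ref == 0
        assert rep.unmatched_est == [(21, 30)]

    def test_partial_overlap_hand_enumeration(self):
        rep = ev.match_intervals(self.make([(1, 5), (9, 9)]), self.make([(4, 6)]))
        assert rep.matched_ref == 1
        assert rep.unmatched_ref == [(9, 9)]
        assert rep.pairs == [((1, 5), (4, 6))]

    def test_tie_goes_to_earliest_reference(self):
        rep = ev.match_intervals(self.make([(0, 2), (4, 6)]), self.make([(2, 4)]))
        assert rep.pairs == [((0, 2), (2, 4))]


class TestFactorInfluence:
    def test_exact_mann_whitney_p(self):
        kappas = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        flags = np.array([True, True, True, False, False, False])
        df = ev.factor_influence(kappas, binary_factors={"group": flags})
        assert df.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)

    def test_monotone_spearman(self):
        kappas = np.linspace(0.4, 0.8, 10)
        age = np.arange(10, 20, 1.0)
        df = ev.factor_influence(kappas, continuous_factors={"age": age})
        assert df.loc[0, "statistic"] == pytest.approx(1.0)

    def test_benjamini_hochberg_step_up(self):
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests([0.01, 0.02, 0.04, 0.5], alpha=0.05,
                                        method="fdr_bh")
        assert list(reject) == [True, True, False, False]

    def test_one_group_factor_skipped_with_warning(self):
        kappas = np.array([0.5, 0.6, 0.7])
        with pytest.warns(UserWarning, match="empty group"):
            df = ev.factor_influence(kappas,
                                     binary_factors={"all_true": np.ones(3, bool)})
        assert len(df) == 0

    def test_joint_bh_across_factor_types(self):
        rng = np.random.default_rng(8)
        kappas = rng.normal(0.7, 0.05, size=30)
        df = ev.factor_influence(
            kappas,
            binary_factors={"b": rng.random(30) > 0.5},
            continuous_factors={"c": rng.normal(size=30)})
        assert {"p_adjusted", "significant"} <= set(df.columns)
        assert len(df) == 2


def test_agreement_report_tasks():
    rng = np.random.default_rng(9)
    refs = [seq(rng.choice(list("WLDR"), size=100)) for _ in range(3)]
    ests = [seq(rng.choice(list("WLDR"), size=100)) for _ in range(3)]
    rep = ev.agreement_report(refs, ests)
    assert set(rep.task) == set(ev.TASKS)
    assert len(rep) == 3 * len(ev.TASKS)
    binary = rep[rep.task.str.startswith("one_vs_rest")]
    assert binary["sensitivity"].notna().all()
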
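"""Tests of segment metrics, regime matrix, alarm scoring and chance-level
statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eeggan import evaluation as ev
from eeggan.cesp import DESK_CESP
from eeggan.synthetic import SeizureTimeline


class TestSegmentMetrics:
    def test_perfect_separation(self):
        m = ev.segment_metrics([.9, .8, .2, .1], [1, 1, 0, 0], 0.5)
        assert (m.sensitivity, m.specificity, m.accuracy, m.auc) == (1, 1, 1, 1)

    def test_reversed_scores_auc_zero(self):
        m = ev.segment_metrics([.1, .2, .8, .9], [1, 1, 0, 0], 0.5)
        assert m.auc == 0.0

    def test_tied_scores_midrank_auc_half(self):
        # hand midrank Mann-Whitney: scores .6/.4 tied across classes
        m = ev.segment_metrics([.6, .4, .6, .4], [1, 0, 0, 1], 0.5)
        assert m.auc == pytest.approx(0.5)

    def test_single_class_auc_absent(self):
        m = ev.segment_metrics([.9, .8], [1, 1], 0.5)
        assert m.auc is None and m.sensitivity == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ev.segment_metrics([.5], [1, 0], 0.5)

    def test_counts_definitions(self):
        m = ev.segment_metrics([.9, .3, .7, .1], [1, 1, 0, 0], 0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)
        assert m.accuracy == 0.5


class TestRegimeSpec:
    def test_sources_follow_name(self):
        s = ev.RegimeSpec("TSTR")
        assert s.train_source == "synthetic" and s.test_source == "real"
        s = ev.RegimeSpec("TRTS")
        assert s.train_source == "real" and s.test_source == "synthetic"

    def test_unknown_name_errors(self):
        with pytest.raises(ValueError):
            ev.RegimeSpec("TXTR")


class TestRegimeMatrix:
    def test_identical_pools_give_identical_trtr_tstr_rows(self, desk_images):
        cfg = dataclasses.replace(DESK_CESP, conv_filters=(4, 4, 4), epochs=3)
        table = ev.run_regime_matrix(desk_images, list(desk_images), cfg,
                                     [ev.RegimeSpec("TRTR"), ev.RegimeSpec("TSTR")])
        a, b = table.loc["TRTR"], table.loc["TSTR"]
        assert a.equals(b)

    def test_test_split_is_time_disjoint_and_reused(self, desk_images):
        train, test = ev.time_disjoint_split(desk_images, 0.25)
        t_train = max(im.t_start for im in train)
        t_test = min(im.t_start for im in test)
        assert t_train < t_test
        assert len(test) == round(0.25 * len(desk_images))

    def test_empty_synthetic_with_tstr_errors(self, desk_images):
        cfg = dataclasses.replace(DESK_CESP, conv_filters=(4, 4, 4), epochs=1)
        with pytest.raises(ValueError, match="synthetic"):
            ev.run_regime_matrix(desk_images, [], cfg, [ev.RegimeSpec("TSTR")])


def make_timeline(duration_h=10.0, onsets_min=(20.0,)):
    return SeizureTimeline(duration_h, [m * 60.0 for m in onsets_min], [])


class TestAlarmEvaluate:
    CFG = ev.AlarmConfig(sph=10.0, sop=30.0, threshold=0.5)

    def test_alarm_predicting_onset_within_sop(self):
        # alarm at t=0, onset 20 min: 10 <= 20 <= 40 -> predicted
        tl = make_timeline(onsets_min=(20.0,))
        res = ev.alarm_evaluate(tl, [0.0], [0.9], self.CFG)
        assert res.n_predicted == 1 and res.false_alarms == 0
        assert res.sensitivity_event == 1.0

    def test_alarm_too_close_to_onset_is_false_alarm(self):
        # onset 5 min after the alarm violates the SPH -> false alarm
        tl = make_timeline(onsets_min=(5.0,))
        res = ev.alarm_evaluate(tl, [0.0], [0.9], self.CFG)
        assert res.n_predicted == 0 and res.false_alarms == 1

    def test_no_alarms(self):
        tl = make_timeline(onsets_min=(60.0, 240.0))
        times = np.arange(0, 10 * 3600, 600.0)
        res = ev.alarm_evaluate(tl, times, np.zeros_like(times), self.CFG)
        assert res.n_predicted == 0 and res.false_alarms == 0
        assert res.sensitivity_event == 0.0 and res.fpr_per_h == 0.0

    def test_refractory_suppresses_double_alarms(self):
        tl = make_timeline(onsets_min=(20.0,))
        times = np.array([0.0, 60.0, 120.0])
        res = ev.alarm_evaluate(tl, times, np.ones(3), self.CFG)
        assert len(res.alarm_times) == 1  # SOP-long refractory

    def test_unsorted_scores_error(self):
        tl = make_timeline()
        with pytest.raises(ValueError, match="sorted"):
            ev.alarm_evaluate(tl, [10.0, 0.0], [0.9, 0.9], self.CFG)

    def test_interictal_hours_excludes_preseizure_windows(self):
        # one onset at 2 h: excluded window (2h - 40min, 2h] -> 9h20m interictal
        tl = make_timeline(duration_h=10.0, onsets_min=(120.0,))
        res = ev.alarm_evaluate(tl, [0.0], [0.0], self.CFG)
        assert res.interictal_hours == pytest.approx(10.0 - 40.0 / 60.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
           st.integers(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    def test_every_alarm_counted_exactly_once(self, scores, n_onsets):
        """Conservation: alarms partition into true predictions + false alarms."""
        onsets = [3600.0 * (4 + 2 * i) for i in range(n_onsets)]
        tl = SeizureTimeline(14.0, onsets, [])
        times = np.arange(len(scores)) * 300.0
        res = ev.alarm_evaluate(tl, times, np.asarray(scores), self.CFG)
        assert res.true_alarms + res.false_alarms == len(res.alarm_times)
        assert 0 <= res.n_predicted <= res.n_seizures


class TestChanceStatistics:
    def test_chance_probability_limits_and_value(self):
        assert ev.chance_probability(0.0, 30.0) == 0.0
        assert ev.chance_probability(1e6, 30.0) == pytest.approx(1.0)
        # FPR 0.27/h, SOP 30 min: 1 - exp(-0.135)
        assert ev.chance_probability(0.27, 30.0) == pytest.approx(0.1262841, abs=1e-6)

    def test_chance_probability_monotone_in_fpr_and_sop(self):
        fprs = np.linspace(0, 5, 30)
        vals = [ev.chance_probability(f, 30.0) for f in fprs]
        assert np.all(np.diff(vals) > 0)
        sops = np.linspace(1, 120, 30)
        vals = [ev.chance_probability(0.3, s) for s in sops]
        assert np.all(np.diff(vals) > 0)

    def test_pvalue_trivial_cases(self):
        assert ev.chance_pvalue(0, 5, 0.7) == 1.0
        assert ev.chance_pvalue(1, 1, 0.3) == pytest.approx(0.3)

    def test_pvalue_term_enumeration(self):
        # N=3, n=2, P=0.2: 3*(0.04)(0.8) + 0.008
        assert ev.chance_pvalue(2, 3, 0.2) == pytest.approx(0.104, abs=1e-9)

    def test_pvalue_matches_enumeration_and_monte_carlo(self):
        """Exact binomial-tail enumeration and a 100k-draw Monte-Carlo oracle
        agree with chance_pvalue on random (n, N, P) triples."""
        from math import comb

        rng = np.random.default_rng(11)
        draws = 100_000
        for _ in range(20):
            N = int(rng.integers(1, 12))
            n = int(rng.integers(0, N + 1))
            P = float(rng.uniform(0.05, 0.95))
            p = ev.chance_pvalue(n, N, P)
            exact = sum(comb(N, k) * P**k * (1 - P) ** (N - k)
                        for k in range(n, N + 1))
            assert p == pytest.approx(exact, abs=1e-12)
            mc = np.mean(rng.binomial(N, P, size=draws) >= n)
            se = max(np.sqrt(exact * (1 - exact) / draws), 1e-6)
            assert abs(mc - p) <= 3 * se + 1e-3

    def test_pvalue_input_validation(self):
        with pytest.raises(ValueError):
            ev.chance_pvalue(3, 2, 0.5)
        with pytest.raises(ValueError):
            ev.chance_pvalue(1, 2, 1.5)
        with pytest.raises(ValueError):
            ev.chance_probability(-0.1, 30.0)

    def test_random_alarms_reject_at_alpha_rate(self):
        """Calibration: alarms raised at random at rate FPR reject the null
        at roughly the significance level."""
        rng = np.random.default_rng(5)
        alpha, rejections, runs = 0.05, 0, 400
        cfg = ev.AlarmConfig(sph=10.0, sop=30.0, threshold=0.5)
        for _ in range(runs):
            onsets = [3600.0 * (5 + 3 * i) for i in range(3)]
            tl = SeizureTimeline(16.0, onsets, [])
            times = np.arange(0, 16 * 3600.0, 1800.0)
            scores = (rng.uniform(size=times.size) < 0.2).astype(float)
            res = ev.alarm_evaluate(tl, times, scores, cfg)
            if res.fpr_per_h > 0 and res.n_seizures:
                t = ev.chance_test(res.n_predicted, res.n_seizures,
                                   res.fpr_per_h, cfg.sop, alpha)
                rejections += t.reject_null
        assert rejections / runs < 3 * alpha + 0.05


class TestHanleyMcNeil:
    def test_equal_aucs_p_half(self):
        assert ev.hanley_mcneil_compare(0.8, 50, 50, 0.8, 50, 50) == pytest.approx(0.5)

    def test_se_closed_form_at_half(self):
        # A=0.5: Q1=1/3, Q2=1/3; SE^2 = (0.25 + (n-1)/12 + (n-1)/12) / n^2
        n = 40
        expected = np.sqrt((0.25 + 2 * (n - 1) * (1 / 3 - 0.25)) / n**2)
        assert ev.hanley_mcneil_se(0.5, n, n) == pytest.approx(expected, rel=1e-12)

    def test_p_decreases_with_sample_size(self):
        ps = [ev.hanley_mcneil_compare(0.8, n, n, 0.7, n, n)
              for n in (20, 50, 100, 400)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p < 0.5 for p in ps)

    def test_degenerate_auc_errors(self):
        with pytest.raises(ValueError, match="exact"):
            ev.hanley_mcneil_se(1.0, 10, 10)

    def test_bonferroni_helper(self):
        assert ev.bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)


class TestRocReport:
    def test_perfect_scores_pass_through_corner(self, tmp_path):
        table = ev.roc_report(
            {"perfect": (np.array([.9, .8, .1, .2]), [1, 1, 0, 0])}, tmp_path)
        pts = np.loadtxt(tmp_path / "roc_perfect.csv", delimiter=",", skiprows=1)
        assert any((fpr == 0 and tpr == 1) for fpr, tpr, _ in pts)
        assert table.loc["perfect", "auc"] == 1.0

    def test_random_scores_near_diagonal(self, tmp_path):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, size=2000)
        table = ev.roc_report({"rand": (scores, list(labels))}, tmp_path)
        assert abs(table.loc["rand", "auc"] - 0.5) < 0.05

    def test_trapezoid_auc_equals_rank_auc(self, tmp_path, rng):
        scores = rng.uniform(size=300)
        labels = rng.integers(0, 2, size=300)
        table = ev.roc_report({"x": (scores, list(labels))}, tmp_path)
        rank = ev.mann_whitney_auc(scores, labels)
        assert table.loc["x", "auc"] == pytest.approx(rank, abs=1e-9)
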
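import numpy as np
import pytest

from dconet.clinical import (
    NO_CONFIDENT_CALLS,
    fit_continuous,
    select_confidence_thresholds,
    survival_evaluation,
    tertile_labels,
)
from dconet.cohort_io import OutcomeTable
from dconet.models import Hyperparameters
from dconet.simulate import PlantedGene, SimulationConfig, simulate_alterations, simulate_pfs


def outcomes(durations, events=None):
    durations = np.asarray(durations, float)
    if events is None:
        events = np.ones(len(durations), int)
    return OutcomeTable([f"p{i}" for i in range(len(durations))], durations, np.asarray(events))


class TestTertiles:
    def test_ordered_small_case(self):
        lab = tertile_labels(outcomes(np.arange(1, 10)))
        assert (lab.lower_cutoff, lab.upper_cutoff) == (3, 7)
        assert set(lab.non_responders) == {"p0", "p1", "p2"}
        assert set(lab.responders) == {"p6", "p7", "p8"}
        assert set(lab.unlabeled) == {"p3", "p4", "p5"}

    def test_all_equal_everything_unlabeled(self):
        with pytest.warns(UserWarning):
            lab = tertile_labels(outcomes(np.full(12, 5.0)))
        assert lab.responders == [] and lab.non_responders == []

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tertile_labels(outcomes(np.arange(1, 9)))

    def test_boundary_ties_go_to_middle(self):
        # value 3 appears in both the lowest third and the middle: tied
        # extreme members are left unlabeled
        lab = tertile_labels(outcomes([1, 2, 3, 3, 4, 5, 7, 8, 9]))
        assert set(lab.non_responders) == {"p0", "p1"}


class TestConfidenceThresholds:
    def test_separated_scores_zero_fdr(self):
        scores = np.array([-2, -1.5, -1, 1, 1.5, 2.0])
        labels = np.array([-1, -1, -1, 1, 1, 1])
        thr = select_confidence_thresholds(scores, labels, max_fdr=0.30)
        assert thr.status == "ok"
        assert thr.fdr_response == 0.0 and thr.fdr_non_response == 0.0
        calls = thr.call(scores)
        assert (calls == labels).all()

    def test_achieved_fdr_never_exceeds_bound(self):
        rng = np.random.default_rng(0)
        for seed in range(30):
            rs = np.random.default_rng(seed)
            labels = np.where(rs.random(60) < 0.5, 1, -1)
            scores = labels * rs.random(60) * 0.5 + rs.normal(0, 0.6, 60)
            thr = select_confidence_thresholds(scores, labels, max_fdr=0.30)
            calls = thr.call(scores)
            if (calls == 1).any():
                fdr = float((labels[calls == 1] == -1).mean())
                assert fdr <= 0.30 + 1e-9
            if (calls == -1).any():
                fdr = float((labels[calls == -1] == 1).mean())
                assert fdr <= 0.30 + 1e-9

    def test_outlier_excluded_by_scan(self):
        # one mislabeled high-score patient: the brute-force scan picks a
        # threshold above it so the response side stays within the bound
        scores = np.array([-1.0, -0.8, -0.6, 2.5, 0.5, 0.6, 0.7, 0.8])
        labels = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
        thr = select_confidence_thresholds(scores, labels, max_fdr=0.20)
        calls = thr.call(scores)
        pred_resp = calls == 1
        assert pred_resp.any()
        assert float((labels[pred_resp] == -1).mean()) <= 0.20

    def test_random_scores_often_no_calls(self):
        sentinel, total_calls = 0, 0
        for seed in range(20):
            rs = np.random.default_rng(seed + 100)
            labels = np.where(rs.random(80) < 0.5, 1, -1)
            scores = rs.normal(0, 1, 80)
            thr = select_confidence_thresholds(scores, labels, max_fdr=0.05)
            if thr.status == NO_CONFIDENT_CALLS:
                sentinel += 1
            else:
                total_calls += int((thr.call(scores) != 0).sum())
        # with uninformative scores a tight bound is regularly unattainable,
        # and whatever qualifies is a handful of lucky extreme scores
        assert sentinel >= 2
        assert total_calls / max(20 - sentinel, 1) <= 10

    def test_monotone_coverage_in_max_fdr(self):
        rs = np.random.default_rng(5)
        labels = np.where(rs.random(60) < 0.5, 1, -1)
        scores = labels * 0.4 + rs.normal(0, 0.7, 60)
        prev = -1
        for fdr in (0.05, 0.15, 0.30, 0.45):
            thr = select_confidence_thresholds(scores, labels, max_fdr=fdr)
            n_calls = int((thr.call(scores) != 0).sum())
            assert n_calls >= prev
            prev = n_calls


class TestSurvivalEvaluation:
    def test_logrank_matches_manual_risk_sets(self):
        # n=6, all events, distinct times; manual risk-set tabulation oracle
        durations = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array([1, -1, 1, -1, 1, -1])
        events = np.ones(6, int)

        # manual log-rank: O-E and variance accumulated over event times
        order = np.argsort(durations)
        at_risk = list(order)
        o_minus_e, var = 0.0, 0.0
        for idx in order:
            n_total = len(at_risk)
            n1 = sum(1 for j in at_risk if groups[j] == 1)
            e1 = n1 / n_total
            o1 = 1.0 if groups[idx] == 1 else 0.0
            o_minus_e += o1 - e1
            if n_total > 1:
                var += (n1 / n_total) * (1 - n1 / n_total)
            at_risk.remove(idx)
        manual_stat = o_minus_e**2 / var

        out = survival_evaluation(groups, durations, events, min_group=3)
        assert out["logrank_statistic"] == pytest.approx(manual_stat, rel=1e-6)

    def test_planted_hazard_ratio_detected(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d1 = rng.exponential(10.0, 50)  # predicted responders: longer PFS
            d0 = rng.exponential(4.0, 50)  # hazard ratio 2.5
            durations = np.concatenate([d1, d0])
            groups = np.array([1] * 50 + [-1] * 50)
            events = np.ones(100, int)
            out = survival_evaluation(groups, durations, events, scores=groups.astype(float))
            if out["logrank_p"] < 0.05:
                hits += 1
            assert out["cox_coef_score"] < 0  # higher score, lower hazard
        assert hits >= int(0.9 * n_seeds)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            survival_evaluation(
                np.array([1, 1, -1, -1]), np.array([1.0, 2, 3, 4]), np.ones(4, int)
            )

    def test_fully_censored_group_median_not_reached(self):
        durations = np.array([5.0] * 6 + [1, 2, 3, 4, 5, 6.0])
        groups = np.array([1] * 6 + [-1] * 6)
        events = np.array([0] * 6 + [1] * 6)
        out = survival_evaluation(groups, durations, events)
        assert np.isinf(out["median_months"]["predicted_response"])


class TestFitContinuous:
    def test_planted_gene_recovered_and_middle_excluded(self):
        cfg = SimulationConfig(
            seed=21,
            n_resp=60,
            n_nonresp=60,
            n_genes=40,
            planted_genes=[PlantedGene("G000", 0.55, 0.05)],
            planted_pairs=[],
        )
        matrix, arm, _ = simulate_alterations(cfg)
        table, _ = simulate_pfs(matrix, cfg)
        labeling = tertile_labels(table)
        bundle, networks = fit_continuous(
            matrix,
            labeling,
            n_permutations=50,
            seed=1,
            hyperparameters=Hyperparameters(),
        )
        assert set(bundle.sample_ids) == set(labeling.responders) | set(labeling.non_responders)
        assert not set(labeling.unlabeled) & set(bundle.sample_ids)
        resp_nodes = networks["Resp"].nodes + networks["General"].nodes
        assert "G000" in resp_nodes

    def test_empty_extreme_group_rejected(self):
        from dconet.clinical import TertileLabeling

        lab = TertileLabeling([f"p{i}" for i in range(10)], [None] * 10, 1.0, 2.0)
        cfg = SimulationConfig(seed=0, n_genes=10, planted_genes=[], planted_pairs=[])
        matrix, _, _ = simulate_alterations(cfg)
        with pytest.raises(ValueError):
            fit_continuous(matrix, lab, n_permutations=10)
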
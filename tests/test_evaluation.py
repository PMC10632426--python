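"""Fold construction, the Mann-Whitney AUROC against a brute-force pair-count
oracle, permutation p-values, deployment consistency and score densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathomil import evaluation, synthetic, training
from pathomil.evaluation import (
    EvalReport,
    auroc,
    auroc_pvalue,
    cross_target_eval,
    cross_validate,
    deploy,
    make_folds,
    max_cdf_gap,
    score_density_summary,
)


def brute_force_auroc(scores, labels):
    """Independent oracle: enumerate every positive-negative pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestFolds:
    def test_balanced_ten_patients(self):
        pids = [f"P{i}" for i in range(10)]
        labels = [1] * 5 + [0] * 5
        plan = make_folds(pids, labels, k=5, seed=0)
        for f in range(5):
            test = plan.test_patients(f)
            assert len(test) == 2
            assert sum(labels[pids.index(p)] for p in test) == 1

    def test_partition_and_tune_disjointness(self):
        rng = np.random.default_rng(1)
        pids = [f"P{i}" for i in range(83)]
        labels = (rng.random(83) < 0.7).astype(int)
        plan = make_folds(pids, labels, k=5, seed=3)
        all_test = [p for f in range(5) for p in plan.test_patients(f)]
        assert sorted(all_test) == sorted(pids)  # partition, no repeats
        for f in range(5):
            train = set(plan.train_patients(f))
            tune = plan.tune_subsets[f]
            test = set(plan.test_patients(f))
            n_train_total = len(train) + len(tune)
            assert len(tune) == round(0.25 * n_train_total)
            assert not tune & test and not train & test and not train & tune

    def test_stratification_within_one_patient(self):
        rng = np.random.default_rng(2)
        labels = (rng.random(100) < 0.75).astype(int)
        pids = [f"P{i}" for i in range(100)]
        plan = make_folds(pids, labels, k=5, seed=0)
        global_pos = labels.sum() / 5
        for f in range(5):
            fold_pos = sum(labels[pids.index(p)] for p in plan.test_patients(f))
            assert abs(fold_pos - global_pos) <= 1

    def test_small_class_error_lists_counts(self):
        with pytest.raises(ValueError, match=r"\[97, 3\]"):
            make_folds([f"P{i}" for i in range(100)], [1] * 3 + [0] * 97, k=5)

    def test_deterministic_per_seed(self):
        pids = [f"P{i}" for i in range(40)]
        labels = [i % 2 for i in range(40)]
        a = make_folds(pids, labels, seed=7)
        b = make_folds(pids, labels, seed=7)
        assert a.assignments == b.assignments and a.tune_subsets == b.tune_subsets


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_two_of_three_concordant_pairs(self):
        # positives 0.9, 0.8, 0.4 vs the single negative 0.7
        assert auroc([0.9, 0.8, 0.4, 0.7], [1, 1, 1, 0]) == pytest.approx(2 / 3)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # quantised scores force ties
        scores = np.round(rng.random(n), 1)
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = (rng.random(60) < 0.5).astype(int)
        scores = rng.random(60)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestPermutationTest:
    def test_perfect_separation_minimal_p(self):
        labels = np.array([1] * 20 + [0] * 20)
        scores = np.concatenate([np.linspace(0.6, 1, 20), np.linspace(0, 0.4, 20)])
        assert auroc_pvalue(scores, labels, n_perm=1000, seed=0) == pytest.approx(1 / 1001)

    def test_deterministic_given_seed(self, rng):
        labels = (rng.random(30) < 0.5).astype(int)
        scores = rng.random(30)
        p1 = auroc_pvalue(scores, labels, seed=4)
        p2 = auroc_pvalue(scores, labels, seed=4)
        assert p1 == p2

    def test_null_p_roughly_uniform(self):
        # under independent labels the p-value should not concentrate near 0
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            labels = np.array([1] * 15 + [0] * 15)
            rng.shuffle(labels)
            ps.append(auroc_pvalue(rng.random(30), labels, n_perm=200,
                                   seed=int(rng.integers(2**31))))
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert rate <= 0.12

    def test_delong_agrees_on_strong_signal(self, rng):
        labels = np.array([1] * 25 + [0] * 25)
        scores = labels + rng.normal(0, 0.3, 50)
        assert evaluation.delong_pvalue(scores, labels) < 0.001


@pytest.fixture(scope="module")
def tiny_cv():
    """A fast, fully-wired CV on an easy cohort (small bags, strong effect)."""
    spec = synthetic.BagSpec(n_patients=40, tiles_per_patient_range=(8, 16),
                             feature_dim=6, witness_rate=0.5, effect_size=3.0,
                             prevalence=0.5, seed=13)
    bags = synthetic.generate_feature_bags(spec)
    cfg = training.TrainConfig(K=8, epochs=4, warmup_epochs=1, batch_patients=16, seed=0)
    models, report, plan, hists = cross_validate(bags, "ER", cfg, seed=0, n_perm=100)
    return bags, models, report, plan


class TestCrossValidate:
    def test_each_patient_scored_exactly_once(self, tiny_cv):
        bags, _, report, _ = tiny_cv
        assert sorted(report.scores["patient_id"]) == sorted(b.patient_id for b in bags)

    def test_report_aggregates_five_folds(self, tiny_cv):
        _, models, report, _ = tiny_cv
        assert len(models) == 5 and len(report.per_model_auroc) == 5
        assert report.mean_auroc == pytest.approx(np.mean(report.per_model_auroc))
        assert 0.0 <= report.mean_auroc <= 1.0 and 0 < report.p_value <= 1.0

    def test_deploy_on_source_reproduces_fold_aurocs(self, tiny_cv):
        bags, models, report, plan = tiny_cv
        dep = deploy(models, bags, "ER", n_perm=50, seed=1)
        by_id = {b.patient_id: b for b in bags}
        for f in range(5):
            test_ids = plan.test_patients(f)
            sub = dep.scores[dep.scores["patient_id"].isin(test_ids)]
            fold_auc = auroc(sub[f"score_model{f}"], sub["label"])
            assert fold_auc == pytest.approx(report.per_model_auroc[f], abs=1e-12)

    def test_extractor_dim_mismatch_rejected(self, tiny_cv):
        _, models, _, _ = tiny_cv
        other = synthetic.generate_feature_bags(
            synthetic.BagSpec(n_patients=10, tiles_per_patient_range=(4, 6),
                              feature_dim=9, prevalence=0.5, seed=1)
        )
        with pytest.raises(ValueError, match="mismatch"):
            deploy(models, other, "ER")


class TestCrossTarget:
    def test_same_target_identical_to_deploy(self, tiny_cv):
        bags, models, _, _ = tiny_cv
        d = deploy(models, bags, "ER", n_perm=50, seed=2)
        x = cross_target_eval(models, bags, "ER", n_perm=50, seed=2)
        assert x.mean_auroc == d.mean_auroc
        pd.testing.assert_series_equal(x.scores["score"], d.scores["score"])

    def test_missing_labels_rejected(self, tiny_cv):
        bags, models, _, _ = tiny_cv
        with pytest.raises(ValueError, match="no labels"):
            cross_target_eval(models, bags, "HER2")


def _report_from_scores(scores, cohort="c", target="ER"):
    n = len(scores)
    labels = np.zeros(n, int)
    labels[: n // 2] = 1
    return EvalReport(
        cohort=cohort, target=target, per_model_auroc=[0.5], mean_auroc=0.5,
        sd_auroc=0.0, p_value=1.0,
        scores=pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                             "label": labels, "score": scores}),
    )


class TestScoreDensity:
    def test_scores_near_one_left_skewed(self, rng):
        scores = 1.0 - rng.beta(1.2, 8.0, size=400)  # piled up near 1
        summary = score_density_summary([_report_from_scores(scores)])
        assert summary["skewness"].iloc[0] < 0

    def test_same_distribution_small_cdf_gap(self):
        # same score distribution in two cohorts => small Kolmogorov gap
        # (sampling fluctuation of the KS statistic is ~0.87*sqrt(2/n))
        rng = np.random.default_rng(3)
        a, b = rng.beta(2, 2, 2000), rng.beta(2, 2, 2000)
        assert max_cdf_gap(a, b) < 0.05

    def test_one_row_block_per_report(self, rng):
        reports = [
            _report_from_scores(rng.random(50), cohort="source"),
            _report_from_scores(rng.random(50), cohort="shifted"),
        ]
        reports[0].normalised = True
        reports[1].normalised = False
        summary = score_density_summary(reports, grid_points=11)
        assert set(summary["cohort"]) == {"source", "shifted"}
        assert len(summary) == 22
        assert summary["density"].min() >= 0
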
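"""LS-SVM solver, AUC, LOOCV layers, nested selection, bootstrap."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from dynconn.classify import (
    CVReport,
    bootstrap_compare,
    loocv_state_auc,
    lssvm_train,
    nested_loocv,
    roc_auc,
    sfnc_nested_loocv,
)


def separable_problem(rng, n=20, p=5, gap=6.0):
    x = rng.standard_normal((n, p))
    y = np.r_[-np.ones(n // 2), np.ones(n - n // 2)]
    x[y == 1] += gap / np.sqrt(p)
    return x, y


class TestLssvmSolver:
    def test_separable_training_signs(self):
        rng = np.random.default_rng(0)
        x, y = separable_problem(rng)
        model = lssvm_train(x, y, C=0.1)
        assert (np.sign(model.decision_values(x)) == y).all()

    @pytest.mark.parametrize("n,p", [(20, 8), (12, 40)])
    def test_dual_equals_primal_ridge(self, n, p):
        """The dual linear system must match the closed-form primal ridge
        solution (penalty 1/C on the weights, unpenalized bias)."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((n, p))
        y = np.sign(rng.standard_normal(n))
        y[0], y[1] = 1, -1
        C = 0.7
        model = lssvm_train(x, y, C=C)
        xa = np.column_stack([x, np.ones(n)])
        penalty = np.eye(p + 1) / C
        penalty[p, p] = 0.0
        sol = np.linalg.solve(xa.T @ xa + penalty, xa.T @ y)
        np.testing.assert_allclose(model.weights, sol[:p], atol=1e-8)
        assert np.isclose(model.bias, sol[p], atol=1e-8)

    def test_duplication_with_paired_c_scaling(self):
        """Duplicating every training point while halving C (the documented
        total-slack scaling) leaves the decision function unchanged."""
        rng = np.random.default_rng(2)
        x, y = separable_problem(rng, n=14, p=6, gap=2.0)
        probe = rng.standard_normal((5, 6))
        m1 = lssvm_train(x, y, C=0.4)
        m2 = lssvm_train(np.vstack([x, x]), np.r_[y, y], C=0.2)
        np.testing.assert_allclose(
            m1.decision_values(probe), m2.decision_values(probe), atol=1e-8
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            lssvm_train(np.zeros((4, 2)), np.ones(4))

    def test_feature_subset_restriction(self):
        rng = np.random.default_rng(3)
        x, y = separable_problem(rng, n=16, p=10)
        idx = np.array([0, 3, 7])
        model = lssvm_train(x, y, feature_index=idx)
        ref = lssvm_train(x[:, idx], y)
        np.testing.assert_allclose(model.weights, ref.weights, atol=1e-10)
        np.testing.assert_allclose(
            model.decision_values(x), ref.decision_values(x[:, idx]), atol=1e-10
        )


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc(np.array([0.1, 0.2, 0.9, 1.0]), np.array([-1, -1, 1, 1])) == 1.0

    def test_chance_level_large_n(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(4000)
        labels = np.r_[np.ones(2000), -np.ones(2000)]
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.standard_normal(200), 1)  # force ties
        labels = np.sign(rng.standard_normal(200))
        labels[labels == 0] = 1
        assert np.isclose(
            roc_auc(scores, labels), roc_auc_score(labels == 1, scores), atol=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal(50)
        labels = np.sign(rng.standard_normal(50))
        labels[labels == 0] = 1
        a = roc_auc(scores, labels)
        assert np.isclose(roc_auc(np.exp(3 * scores), labels), a, atol=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestLoocv:
    def test_identical_class_prototypes_give_auc_one(self):
        proto = np.random.default_rng(7).standard_normal(6)
        x = np.vstack([proto, proto, -proto, -proto])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        auc, _ = loocv_state_auc(x, y, standardize=False)
        assert auc == 1.0

    def test_too_small_roster_raises(self):
        with pytest.raises(ValueError):
            loocv_state_auc(np.zeros((3, 2)), np.array([1.0, -1.0, 1.0]))


class TestNestedLoocv:
    def make_two_state_problem(self, rng, n=16, p=30, gap=1.5):
        ids = [f"s{i}" for i in range(n)]
        labels = {sid: (1 if i >= n // 2 else -1) for i, sid in enumerate(ids)}
        feats = {}
        for s in range(2):
            x = rng.standard_normal((n, p))
            if s == 1:  # informative state
                x[n // 2 :, : p // 3] += gap / np.sqrt(p // 3)
            feats[s] = (list(ids), x)
        return feats, labels

    def test_single_state_zero_threshold_reduces_to_plain_loocv(self):
        rng = np.random.default_rng(8)
        n, p = 14, 12
        ids = [f"s{i}" for i in range(n)]
        x = rng.standard_normal((n, p))
        y = {sid: (1 if i % 2 else -1) for i, sid in enumerate(ids)}
        report = nested_loocv({0: (ids, x)}, y, thresholds=[0.0])
        plain_auc, _ = loocv_state_auc(
            x, np.array([y[s] for s in ids], dtype=float)
        )
        assert np.isclose(report.overall_auc, plain_auc, atol=1e-12)

    def test_candidate_count_is_states_times_thresholds(self):
        rng = np.random.default_rng(9)
        n = 16
        ids = [f"s{i}" for i in range(n)]
        labels = {sid: (1 if i % 2 else -1) for i, sid in enumerate(ids)}
        feats = {}
        for s in range(4):
            x = rng.standard_normal((n, 10))
            x[1::2] += 3.0  # informative everywhere so every threshold is usable
            feats[s] = (list(ids), x)
        report = nested_loocv(feats, labels)
        assert all(f["n_candidates"] == 24 for f in report.per_fold_choice)

    def test_informative_state_preferred(self):
        rng = np.random.default_rng(10)
        feats, labels = self.make_two_state_problem(rng, n=20, gap=4.0)
        report = nested_loocv(feats, labels)
        modal = max(report.selection_histogram, key=report.selection_histogram.get)
        assert modal[0] == 1
        assert report.overall_auc > 0.8

    def test_no_leakage_under_feature_poisoning(self):
        """Perturbing the held-out subject's features must not change the
        model chosen for that subject's fold."""
        rng = np.random.default_rng(11)
        feats, labels = self.make_two_state_problem(rng, n=16, gap=1.5)
        baseline = nested_loocv(feats, labels)
        victim = "s3"
        poisoned = {}
        for s, (ids, x) in feats.items():
            x2 = x.copy()
            x2[ids.index(victim)] *= 100.0
            poisoned[s] = (ids, x2)
        altered = nested_loocv(poisoned, labels)
        base_choice = next(
            f for f in baseline.per_fold_choice if f["subject_id"] == victim
        )
        new_choice = next(
            f for f in altered.per_fold_choice if f["subject_id"] == victim
        )
        assert (base_choice["state"], base_choice["threshold"]) == (
            new_choice["state"],
            new_choice["threshold"],
        )
        assert base_choice["inner_auc"] == new_choice["inner_auc"]

    def test_subject_visiting_no_state_excluded(self):
        rng = np.random.default_rng(12)
        ids = [f"s{i}" for i in range(9)]
        labels = {sid: (1 if i % 2 else -1) for i, sid in enumerate(ids)}
        feats = {0: (ids[:-1], rng.standard_normal((8, 5)))}
        report = nested_loocv(feats, labels)
        assert report.excluded == [ids[-1]]
        assert {f["subject_id"] for f in report.per_fold_choice} == set(ids[:-1])

    def test_outer_t_mode_runs(self):
        rng = np.random.default_rng(13)
        feats, labels = self.make_two_state_problem(rng)
        report = nested_loocv(feats, labels, t_mode="outer")
        assert 0.0 <= report.overall_auc <= 1.0

    def test_sfnc_wrapper_single_state(self):
        rng = np.random.default_rng(14)
        n = 12
        ids = [f"s{i}" for i in range(n)]
        labels = {sid: (1 if i % 2 else -1) for i, sid in enumerate(ids)}
        report = sfnc_nested_loocv(rng.standard_normal((n, 15)), ids, labels)
        assert {s for s, _ in report.selection_histogram} == {0}

    def test_determinism(self):
        rng = np.random.default_rng(15)
        feats, labels = self.make_two_state_problem(rng)
        r1 = nested_loocv(feats, labels)
        r2 = nested_loocv(feats, labels)
        assert r1.overall_auc == r2.overall_auc
        assert r1.selection_histogram == r2.selection_histogram
        assert r1.pooled_scores == r2.pooled_scores


def make_report(rng, n=96, signal=1.0):
    scores = rng.standard_normal(n)
    labels = np.r_[-np.ones(n // 2), np.ones(n - n // 2)].astype(int)
    scores[labels == 1] += signal
    pooled = {f"s{i}": (float(scores[i]), int(labels[i])) for i in range(n)}
    return CVReport(
        per_state_auc={},
        overall_auc=roc_auc(scores, labels),
        per_fold_choice=[],
        selection_histogram={},
        pooled_scores=pooled,
    )


class TestBootstrap:
    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(16)
        rep = make_report(rng)
        out = bootstrap_compare(rep, rep, n_boot=50, seed=0)
        assert out["df"] == 98

    def test_identical_reports_not_significant(self):
        rng = np.random.default_rng(17)
        rep = make_report(rng)
        out = bootstrap_compare(rep, rep, n_boot=400, seed=1)
        assert out["p"] > 0.05

    def test_bootstrap_mean_near_point_auc(self):
        rng = np.random.default_rng(18)
        rep = make_report(rng, n=96, signal=1.5)
        out = bootstrap_compare(rep, rep, n_boot=1000, seed=2)
        assert abs(out["auc_samples_a"].mean() - rep.overall_auc) < 0.02

    def test_detects_real_difference(self):
        rng = np.random.default_rng(19)
        good = make_report(rng, signal=2.5)
        bad = make_report(rng, signal=0.2)
        out = bootstrap_compare(good, bad, n_boot=400, seed=3)
        assert out["t"] > 0 and out["p"] < 1e-6
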
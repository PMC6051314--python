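"""Group statistics: pooled t, Fisher exact, BH-FDR, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import hypergeom

from dynconn.stats import (
    covariate_regression,
    demographics_table,
    fdr_bh,
    fisher_exact_2x2,
    pooled_t_vector,
    statewise_group_diff,
    two_sample_t,
    two_sample_t_from_summary,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(a, a)
        assert t == 0.0 and np.isclose(p, 1.0)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert np.isclose(t1, -t2) and np.isclose(p1, p2)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(15), rng.standard_normal(20) + 0.3
        t, p = two_sample_t(a, b)
        ref = sps.ttest_ind(b, a, equal_var=True)
        assert np.isclose(t, ref.statistic) and np.isclose(p, ref.pvalue)

    def test_matches_permutation_p(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 0.4
        t_obs, p_t = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, 30)), axis=1)
        perm = pooled[idx]
        diffs = perm[:, 15:].mean(axis=1) - perm[:, :15].mean(axis=1)
        obs = b.mean() - a.mean()
        p_perm = np.mean(np.abs(diffs) >= abs(obs))
        assert abs(p_perm - p_t) < 0.02

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            two_sample_t(np.ones(5), np.ones(5))


class TestSummaryT:
    @pytest.mark.parametrize(
        "row, expected_t",
        [
            ((27.40, 8.96, 48, 27.79, 9.18, 48), 0.21),
            ((13.92, 2.13, 48, 13.13, 2.25, 48), -1.77),
            ((57.70, 6.51, 20, 47.65, 9.76, 26), -3.97),
            ((13.92, 2.17, 26, 12.58, 2.39, 24), -2.08),
        ],
    )
    def test_cohort_table_rows(self, row, expected_t):
        """Pooled t recomputed from published cohort summary rows."""
        t, _ = two_sample_t_from_summary(*row)
        assert round(t, 2) == expected_t

    def test_equal_means_give_zero(self):
        t, p = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and np.isclose(p, 1.0)

    def test_consistent_with_sample_version(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(9), rng.standard_normal(14) + 1
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert np.isclose(t1, t2) and np.isclose(p1, p2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(0, 1, 1, 0, 1, 5)
        with pytest.raises(ValueError):
            two_sample_t_from_summary(0, 0, 5, 0, 1, 5)


class TestFisherExact:
    def test_balanced_sex_table(self):
        assert fisher_exact_2x2(np.array([[23, 25], [23, 25]])) == 1.0

    def test_identical_rows_give_one(self):
        assert fisher_exact_2x2(np.array([[7, 3], [7, 3]])) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        table = np.array([[21, 22], [16, 21]])
        p = fisher_exact_2x2(table)
        # two-sided point-probability method by direct enumeration
        a, b = table[0]
        c, d = table[1]
        n, k1, k2 = a + b + c + d, a + b, a + c
        support = np.arange(max(0, k1 + k2 - n), min(k1, k2) + 1)
        probs = hypergeom.pmf(support, n, k1, k2)
        p_obs = hypergeom.pmf(a, n, k1, k2)
        expected = probs[probs <= p_obs * (1 + 1e-12)].sum()
        assert np.isclose(p, expected, atol=1e-12)
        assert round(p, 2) == 0.66

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[-1, 2], [3, 4]]))


class TestFdrBh:
    def test_all_zero_all_significant(self):
        mask, adj = fdr_bh(np.zeros(10))
        assert mask.all() and (adj == 0).all()

    def test_all_one_none_significant(self):
        mask, _ = fdr_bh(np.ones(10))
        assert not mask.any()

    def test_matches_step_up_loop(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=1128) ** 2
        mask, _ = fdr_bh(p, alpha=0.05)
        # literal Benjamini-Hochberg step-up
        order = np.argsort(p)
        m = len(p)
        largest = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.05 * rank / m:
                largest = rank
        expected = np.zeros(m, dtype=bool)
        expected[order[:largest]] = True
        np.testing.assert_array_equal(mask, expected)

    def test_never_more_than_uncorrected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=200)
            mask, _ = fdr_bh(p, alpha=0.05)
            assert mask.sum() <= (p <= 0.05).sum()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestVectorizedT:
    def test_matches_scalar_version_per_column(self):
        rng = np.random.default_rng(6)
        xa, xb = rng.standard_normal((12, 5)), rng.standard_normal((9, 5)) + 0.4
        t, p = pooled_t_vector(xa, xb)
        for j in range(5):
            tj, pj = two_sample_t(xa[:, j], xb[:, j])
            assert np.isclose(t[j], tj) and np.isclose(p[j], pj)


class TestStatewise:
    def test_effect_found_only_in_effect_state(self, tiny_run):
        eff_latent = tiny_run.config.effect_state
        inv = {v: k for k, v in tiny_run.cluster_to_latent.items()}
        eff_cluster = inv[eff_latent]
        for res in tiny_run.group_stats:
            hits = np.flatnonzero(res.fdr_mask)
            if res.state == eff_cluster:
                assert set(hits) <= set(range(res.t_values.size))
            else:
                assert len(hits) <= 1  # null states: at most stray noise

    def test_untested_state_flagged(self):
        rng = np.random.default_rng(7)

        class Model:
            k = 1
            centroids = np.zeros((1, 3))

            def __init__(self):
                self.subject_state_means = {
                    "a": {0: rng.standard_normal(3)},
                    "b": {0: rng.standard_normal(3)},
                    "c": {0: rng.standard_normal(3)},
                }

            def roster(self, s):
                return list(self.subject_state_means)

        phen = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "group": ["control", "control", "patient"],
            }
        )
        results = statewise_group_diff(Model(), phen)
        assert not results[0].tested


class TestRegression:
    def make_phen(self, n, rng):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["control"] * (n // 2) + ["patient"] * (n - n // 2),
                "sex": rng.choice(["M", "F"], n),
                "age": rng.normal(28, 9, n),
                "edu": rng.normal(14, 2, n),
                "wtar": rng.normal(52, 8, n),
            }
        )

    def test_exact_linear_response(self):
        rng = np.random.default_rng(8)
        phen = self.make_phen(40, rng)
        betas, pvals = covariate_regression(2.0 * phen["age"].to_numpy(), phen)
        assert np.isclose(betas["age"], 2.0, atol=1e-10)
        for other in ("sex", "edu", "wtar"):
            assert abs(betas[other]) < 1e-10

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        phen = self.make_phen(30, rng)
        y = rng.standard_normal(30)
        betas, _ = covariate_regression(y, phen)
        x = np.column_stack(
            [
                np.ones(30),
                (phen["sex"] == "M").astype(float),
                phen["age"],
                phen["edu"],
                phen["wtar"],
            ]
        )
        expected = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(betas.to_numpy(), expected, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(10)
        phen = self.make_phen(25, rng)
        phen["wtar"] = phen["edu"]
        with pytest.raises(ValueError, match="collinear"):
            covariate_regression(rng.standard_normal(25), phen)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        phen = self.make_phen(60, rng)
        pvals = [
            covariate_regression(rng.standard_normal(60), phen)[1]["age"]
            for _ in range(200)
        ]
        pvals = np.array(pvals)
        assert 0.4 < pvals.mean() < 0.6
        assert abs((pvals < 0.05).mean() - 0.05) < 0.05


class TestDemographics:
    def test_table_layout_and_balanced_sex(self):
        rng = np.random.default_rng(12)
        n = 24
        phen = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["control"] * 12 + ["patient"] * 12,
                "sex": ["M", "F"] * 12,
                "age": rng.normal(28, 9, n),
                "edu": rng.normal(14, 2, n),
                "wtar": rng.normal(52, 8, n),
            }
        )
        table = demographics_table(phen, {"all": phen["subject_id"].tolist()})
        assert list(table["variable"]) == ["sex", "age", "edu", "wtar"]
        sex_row = table[table["variable"] == "sex"].iloc[0]
        assert sex_row["p_value"] == 1.0
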
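import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perfmap import CohortConfig, simulate_cohort
from perfmap.pls import (dominance_analysis, impute_mode_by_group, pls_bootstrap,
                         pls_crossval, pls_fit, pls_permutation, zscore_columns)


@pytest.fixture(scope="module")
def coupled_cohort():
    return simulate_cohort(CohortConfig(n_subjects=300, coupling=0.8, seed=7))


class TestPlsFit:
    def test_single_column_y(self):
        rng = np.random.default_rng(0)
        model = pls_fit(rng.standard_normal((30, 5)), rng.standard_normal((30, 1)))
        assert model.covariance_explained.shape == (1,)
        assert model.covariance_explained[0] == pytest.approx(1.0)

    def test_matches_manual_svd_pipeline(self):
        """Oracle: z-score columns, SVD of X'Y, explained = s^2 / sum s^2."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 7)) * 3 + 1
        y = rng.standard_normal((40, 4))
        model = pls_fit(x, y)
        xz = stats.zscore(x, ddof=1)
        yz = stats.zscore(y, ddof=1)
        s_ref = np.linalg.svd(xz.T @ yz, compute_uv=False)
        assert np.allclose(np.sort(model.S), np.sort(s_ref), atol=1e-10)
        assert np.allclose(model.covariance_explained,
                           s_ref ** 2 / np.sum(s_ref ** 2), atol=1e-12)

    def test_constructed_singular_values(self):
        """Singular values (2, 1) give covariance explained (0.8, 0.2)."""
        s = np.array([2.0, 1.0])
        assert np.allclose(s ** 2 / np.sum(s ** 2), [0.8, 0.2])
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 3))
        y = rng.standard_normal((200, 2))
        model = pls_fit(x, y)
        assert model.covariance_explained.sum() == pytest.approx(1.0)

    def test_scores_reproduce_definitions(self):
        rng = np.random.default_rng(3)
        model = pls_fit(rng.standard_normal((25, 6)), rng.standard_normal((25, 3)))
        assert np.allclose(model.brain_scores, model.X @ model.U, atol=1e-12)
        assert np.allclose(model.biomarker_scores, model.Y @ model.V, atol=1e-12)
        assert np.allclose(model.U.T @ model.U, np.eye(model.U.shape[1]), atol=1e-8)
        assert np.allclose(model.V.T @ model.V, np.eye(model.V.shape[1]), atol=1e-8)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 5))
        y = rng.standard_normal((30, 3))
        base = pls_fit(x, y)
        x2 = x * np.array([2.0, 0.5, 7.0, 1.0, 3.0]) + np.array([1, 2, 3, 4, 5])
        scaled = pls_fit(x2, y)
        assert np.allclose(base.S, scaled.S, atol=1e-10)
        assert np.allclose(np.abs(base.U), np.abs(scaled.U), atol=1e-8)

    def test_constant_column_named(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 3))
        x[:, 1] = 4.0
        with pytest.raises(ValueError, match=r"X: \[1\]"):
            pls_fit(x, rng.standard_normal((20, 2)))


class TestPlsPermutation:
    def test_single_permutation_convention(self):
        rng = np.random.default_rng(6)
        model = pls_fit(rng.standard_normal((20, 4)), rng.standard_normal((20, 2)))
        p = pls_permutation(model, n_perm=1, seed=0)
        assert set(np.round(p, 10)) <= {0.5, 1.0}

    def test_planted_coupling_is_extreme(self, coupled_cohort):
        model = pls_fit(coupled_cohort.values,
                        coupled_cohort.biomarkers.to_numpy())
        p = pls_permutation(model, n_perm=1000, seed=1)
        assert p[0] == pytest.approx(1 / 1001)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        p1 = []
        for seed in range(100):
            x = rng.standard_normal((50, 10))
            y = rng.standard_normal((50, 4))
            model = pls_fit(x, y)
            p1.append(pls_permutation(model, n_perm=200, seed=seed)[0])
        assert stats.kstest(p1, "uniform").statistic < 0.15

    def test_invalid_nperm(self, coupled_cohort):
        model = pls_fit(coupled_cohort.values[:20, :10],
                        coupled_cohort.biomarkers.to_numpy()[:20])
        with pytest.raises(ValueError):
            pls_permutation(model, n_perm=0)


class TestPlsBootstrap:
    def test_coupled_biomarkers_are_stable(self, coupled_cohort):
        model = pls_fit(coupled_cohort.values,
                        coupled_cohort.biomarkers.to_numpy())
        boot = pls_bootstrap(model, n_boot=1000, seed=2)
        names = list(coupled_cohort.biomarkers.columns)
        coupled = [names.index(n) for n in coupled_cohort.truth["coupled_biomarkers"]]
        br = boot["y_bootstrap_ratios"][:, 0]
        assert np.mean(np.abs(br[coupled]) >= 2) >= 0.9

    def test_degenerate_resampling_hits_sentinel(self):
        rng = np.random.default_rng(8)
        model = pls_fit(rng.standard_normal((15, 4)), rng.standard_normal((15, 2)))
        with pytest.warns(RuntimeWarning, match="zero bootstrap sd"):
            boot = pls_bootstrap(model, n_boot=5, seed=0,
                                 _resampler=lambda rng, n: np.arange(n))
        assert np.all(np.isinf(boot["y_bootstrap_ratios"]))


class TestPlsCrossval:
    def test_planted_coupling_generalizes(self, coupled_cohort):
        cv = pls_crossval(coupled_cohort.values,
                          coupled_cohort.biomarkers.to_numpy(),
                          n_splits=100, n_perm=100, seed=3)
        assert cv.mean_r >= 0.2
        assert cv.p < 0.05

    def test_independent_blocks_center_on_zero(self):
        rng = np.random.default_rng(9)
        means = []
        for seed in range(20):
            x = rng.standard_normal((60, 15))
            y = rng.standard_normal((60, 5))
            cv = pls_crossval(x, y, n_splits=20, n_perm=1, seed=seed)
            means.append(cv.mean_r)
        assert abs(np.mean(means)) <= 0.1

    def test_single_split_reproducible(self, coupled_cohort):
        kwargs = dict(n_splits=1, n_perm=1, seed=5)
        a = pls_crossval(coupled_cohort.values,
                         coupled_cohort.biomarkers.to_numpy(), **kwargs)
        b = pls_crossval(coupled_cohort.values,
                         coupled_cohort.biomarkers.to_numpy(), **kwargs)
        assert a.mean_r == b.mean_r

    def test_invalid_train_fraction(self, coupled_cohort):
        with pytest.raises(ValueError):
            pls_crossval(coupled_cohort.values,
                         coupled_cohort.biomarkers.to_numpy(), train_fraction=1.2)


class TestDominance:
    def test_single_predictor_equals_r2(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((50, 1))
        y = 2 * x[:, 0] + rng.standard_normal(50)
        res = dominance_analysis(x, y)
        r2 = np.corrcoef(x[:, 0], y)[0, 1] ** 2
        assert res.contributions[0] == pytest.approx(r2, abs=1e-10)

    def test_orthogonal_equal_predictors_split_evenly(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + x2
        res = dominance_analysis(np.column_stack([x1, x2]), y)
        assert res.total_r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.contributions, [0.5, 0.5], atol=1e-12)

    def test_contributions_sum_to_total_r2(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((60, 4))
        y = x @ [1.0, 0.5, 0.0, -0.3] + rng.standard_normal(60)
        res = dominance_analysis(x, y)
        assert res.contributions.sum() == pytest.approx(res.total_r2, abs=1e-10)

    def test_matches_shapley_ordering_oracle(self):
        """Total dominance equals the Shapley value over predictor orderings."""
        from itertools import permutations
        rng = np.random.default_rng(12)
        p = 4
        x = rng.standard_normal((40, p))
        y = x @ rng.standard_normal(p) + rng.standard_normal(40)
        res = dominance_analysis(x, y)

        def r2_of(sub):
            if not sub:
                return 0.0
            d = np.column_stack([np.ones(40), x[:, list(sub)]])
            b, *_ = np.linalg.lstsq(d, y, rcond=None)
            return 1 - np.sum((y - d @ b) ** 2) / np.sum((y - y.mean()) ** 2)

        shapley = np.zeros(p)
        for order in permutations(range(p)):
            seen = []
            for i in order:
                shapley[i] += r2_of(seen + [i]) - r2_of(seen)
                seen.append(i)
        import math
        shapley /= math.factorial(p)
        assert np.allclose(res.contributions, shapley, atol=1e-10)

    def test_too_many_predictors_rejected(self):
        with pytest.raises(ValueError, match="20"):
            dominance_analysis(np.zeros((30, 21)), np.zeros(30))


class TestImputation:
    def test_mode_within_sex_group(self):
        tab = pd.DataFrame({"a": [1.0, 1.0, np.nan, 5.0, 5.0, np.nan]})
        groups = [0, 0, 0, 1, 1, 1]
        out = impute_mode_by_group(tab, groups)
        assert out["a"].tolist() == [1.0, 1.0, 1.0, 5.0, 5.0, 5.0]

    def test_all_missing_group_rejected(self):
        tab = pd.DataFrame({"a": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError, match="all-missing"):
            impute_mode_by_group(tab, [0, 0, 1])
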
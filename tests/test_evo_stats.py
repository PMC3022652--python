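"""evo_stats: correlations, variance partitioning, PCR, group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eppid.errors import ValidationError
from eppid.evo_stats import (
    fisher_exact_2x2,
    group_tests,
    partial_spearman,
    pcr,
    spearman,
    variance_explained,
    variance_explained_controlled,
    wilcoxon_one_sided,
)


def _average_ranks(values):
    """Brute-force average ranks (oracle for tie handling)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = np.exp(x) + 0.01 * rng.standard_normal(50)
        assert spearman(x, y).rho == pytest.approx(spearman(x, np.log(y + 10)).rho)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversed_sequence(self):
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ties_match_bruteforce_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 20).astype(float)  # heavy ties
        y = rng.integers(0, 4, 20).astype(float)
        expected = np.corrcoef(_average_ranks(x), _average_ranks(y))[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-9)

    def test_constant_vector_is_na(self):
        res = spearman([1.0] * 10, list(range(10)))
        assert math.isnan(res.rho)


class TestPartialSpearman:
    def test_independent_control_leaves_rho_unchanged(self):
        rng = np.random.default_rng(10)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        ctrl = rng.standard_normal(n)
        plain = spearman(x, y).rho
        partial = partial_spearman(x, y, ctrl).rho
        assert partial == pytest.approx(plain, abs=0.03)

    def test_control_equal_to_y_is_degenerate(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        with pytest.raises(ValidationError, match="collinear"):
            partial_spearman(x, y, y)

    def test_shared_driver_partials_to_zero(self):
        rng = np.random.default_rng(12)
        n = 10_000
        ctrl = rng.standard_normal(n)
        x = ctrl + 0.4 * rng.standard_normal(n)
        y = np.exp(ctrl) + 0.4 * rng.standard_normal(n)
        assert abs(spearman(x, y).rho) > 0.5
        assert partial_spearman(x, y, ctrl).rho == pytest.approx(0.0, abs=0.05)


class TestVarianceExplained:
    def test_exact_linear_relation(self):
        x = np.arange(20.0)
        pct, p = variance_explained(x, 2 * x)
        assert pct == pytest.approx(100.0)
        assert p < 1e-20

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        pct, _ = variance_explained(x, y)
        assert pct == pytest.approx(100 * np.corrcoef(x, y)[0, 1] ** 2, rel=1e-9)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(5)
        pct, _ = variance_explained(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert pct < 0.1

    def test_log_transform_with_constant(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.log(x + 0.1)
        pct, _ = variance_explained(x, y, log_x=True, const_x=0.1)
        assert pct == pytest.approx(100.0)


class TestVarianceExplainedControlled:
    def test_predictor_equal_to_control_explains_nothing(self):
        rng = np.random.default_rng(6)
        ctrl = rng.standard_normal(500)
        y = 2 * ctrl + rng.standard_normal(500)
        pct, _ = variance_explained_controlled(ctrl, y, ctrl)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_control_changes_little(self):
        rng = np.random.default_rng(7)
        n = 5_000
        x = rng.standard_normal(n)
        ctrl = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        raw, _ = variance_explained(x, y)
        ctl, _ = variance_explained_controlled(x, y, ctrl)
        assert ctl == pytest.approx(raw, abs=1.5)

    def test_response_fully_determined_by_control(self):
        rng = np.random.default_rng(8)
        ctrl = rng.standard_normal(300)
        x = rng.standard_normal(300)
        pct, _ = variance_explained_controlled(x, 3 * ctrl + 1, ctrl)
        assert pct == pytest.approx(0.0, abs=1e-9)


class TestPCR:
    def _toy(self, n=2000, seed=0, k=6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, k)), columns=[f"v{i}" for i in range(k)]
        )
        return rng, X

    def test_two_variable_contributions_are_closed_form(self):
        # any 2x2 correlation matrix has eigenvectors (1,±1)/sqrt(2): all 50%
        rng, X = self._toy(k=2)
        X["v1"] = 0.4 * X["v0"] + 0.9 * X["v1"]
        y = pd.Series(X["v0"] + 0.1 * rng.standard_normal(len(X)))
        res = pcr(X, y, no_log=tuple(X.columns), response_log=False)
        np.testing.assert_allclose(res.contribution_pct.to_numpy(), 50.0, atol=1e-8)

    def test_contribution_columns_sum_to_100(self):
        rng, X = self._toy(seed=1)
        X = X.add(5.0)  # keep positive for log transform
        y = pd.Series(np.exp(rng.standard_normal(len(X))))
        res = pcr(X, y)
        np.testing.assert_allclose(
            res.contribution_pct.sum(axis=0), 100.0, atol=1e-8
        )

    def test_component_variances_sum_to_full_ols_r2(self):
        rng, X = self._toy(seed=2)
        y = pd.Series(
            X["v0"] - 0.5 * X["v3"] + rng.standard_normal(len(X)), name="y"
        )
        res = pcr(X, y, no_log=tuple(X.columns), response_log=False)
        # independent oracle: ordinary least squares on the raw predictors
        Z = (X - X.mean()) / X.std(ddof=1)
        design = np.column_stack([np.ones(len(X)), Z.to_numpy()])
        beta, *_ = np.linalg.lstsq(design, y.to_numpy(), rcond=None)
        fitted = design @ beta
        ss_res = np.sum((y.to_numpy() - fitted) ** 2)
        ss_tot = np.sum((y.to_numpy() - y.mean()) ** 2)
        r2_pct = 100 * (1 - ss_res / ss_tot)
        assert res.total_variance_pct == pytest.approx(r2_pct, rel=1e-6)

    def test_single_driver_dominates_one_component(self):
        # v0 independent of a correlated v1..v5 block, so one eigenvector
        # aligns with v0 up to sampling error and carries the whole signal
        rng, X = self._toy(n=5000, seed=3)
        shared = rng.standard_normal(len(X))
        for col in X.columns[1:]:
            X[col] = math.sqrt(0.4) * shared + math.sqrt(0.6) * X[col]
        y = pd.Series(2.0 * X["v0"] + 0.05 * rng.standard_normal(len(X)))
        res = pcr(X, y, no_log=tuple(X.columns), response_log=False)
        top = int(np.argmax(res.component_variance_pct))
        assert res.component_variance_pct[top] > 0.95 * res.total_variance_pct
        assert res.contribution_pct.iloc[:, top].idxmax() == "v0"

    def test_loadings_match_sklearn_pca(self):
        from sklearn.decomposition import PCA

        rng, X = self._toy(seed=4)
        X["v1"] = 0.7 * X["v0"] + 0.5 * X["v1"]
        X["v4"] = -0.6 * X["v2"] + 0.8 * X["v4"]
        y = pd.Series(rng.standard_normal(len(X)))
        res = pcr(X, y, no_log=tuple(X.columns), response_log=False)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        pca = PCA(n_components=X.shape[1]).fit(Z)
        # squared loadings are sign- and order-robust up to eigenvalue ties
        ours = np.sort(res.contribution_pct.to_numpy(), axis=1)
        theirs = np.sort(100 * pca.components_.T**2, axis=1)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_collinear_predictors_rejected(self):
        rng, X = self._toy(k=3)
        X["v2"] = X["v0"] + X["v1"]
        y = pd.Series(rng.standard_normal(len(X)))
        with pytest.raises(ValidationError, match="collinear|singular"):
            pcr(X, y, no_log=tuple(X.columns), response_log=False)

    def test_significance_codes(self):
        rng, X = self._toy(seed=5)
        y = pd.Series(X["v0"] + rng.standard_normal(len(X)))
        res = pcr(X, y, no_log=tuple(X.columns), response_log=False)
        codes = res.significance_codes()
        assert codes[int(np.argmax(res.component_variance_pct))] == "***"


class TestGroupTests:
    def test_identical_groups_near_half(self):
        rng = np.random.default_rng(20)
        values = rng.standard_normal(200)
        p = wilcoxon_one_sided(values, values.copy())
        assert p == pytest.approx(0.5, abs=0.01)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(21)
        a = rng.standard_normal(200) - 0.5
        b = rng.standard_normal(200)
        assert wilcoxon_one_sided(a, b) < 0.01
        assert wilcoxon_one_sided(b, a) > 0.5

    def test_fisher_diagonal_table(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("table", [[[3, 7], [5, 2]], [[8, 1], [2, 9]], [[4, 4], [4, 4]]])
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        (a, b), (c, d) = table
        n, row1, col1 = a + b + c + d, a + b, a + c
        probs = {
            k: stats.hypergeom.pmf(k, n, row1, col1)
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        }
        p_two_sided = sum(v for v in probs.values() if v <= probs[a] * (1 + 1e-9))
        assert fisher_exact_2x2(table) == pytest.approx(p_two_sided, rel=1e-9)

    def test_group_tests_table_shape(self):
        rng = np.random.default_rng(22)
        groups = {"a": rng.standard_normal(30) - 1, "b": rng.standard_normal(30)}
        out = group_tests(groups)
        assert len(out) == 2
        p_ab = out.loc[(out.lower_group == "a"), "p"].iloc[0]
        assert p_ab < 0.05
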
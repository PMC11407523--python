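"""Dynamic-feature selection (cubic regression + stepwise + BH) and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidyn.dynamics import (
    DynamicFeatureModel,
    backward_stepwise,
    benjamini_hochberg,
    fit_polynomial_timecourse,
    fuzzy_cmeans,
    hierarchical_cluster_profiles,
    select_dynamic_features,
)
from lipidyn.quantify import Units

from conftest import matrix_from_values, study_design


@pytest.fixture(scope="module")
def times(design):
    return np.array([m.stage_code for m in design], dtype=float)


class TestPolynomialFit:
    def test_exact_cubic_has_r2_one(self, times):
        y = 0.5 * times**3 - 2 * times**2 + times
        fit = fit_polynomial_timecourse(y, times)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.global_pvalue < 1e-12

    def test_constant_response_is_non_testable(self, times):
        fit = fit_polynomial_timecourse(np.ones_like(times), times)
        assert not fit.testable

    def test_too_few_distinct_times(self):
        with pytest.raises(ValueError):
            fit_polynomial_timecourse([1, 2, 3, 4], [1, 1, 2, 2])

    def test_coefficients_match_normal_equations(self):
        # independent least-squares oracle on a 7-point design
        t = np.array([1, 5, 8, 10, 11, 13, 15], dtype=float)
        rng = np.random.default_rng(42)
        y = rng.normal(size=7)
        fit = fit_polynomial_timecourse(y, t, standardize=False)
        tc = t - t.mean()
        X = np.column_stack([np.ones(7), tc, tc**2, tc**3])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [fit.coefficients[k] for k in ("intercept", "t", "t2", "t3")]
        assert np.allclose(got, beta)
        resid = y - X @ beta
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(r2)


class TestBackwardStepwise:
    def test_linear_signal_keeps_only_linear_term(self, times):
        rng = np.random.default_rng(0)
        y = times + rng.normal(0, 0.05, size=len(times))
        fit = backward_stepwise(y, times)
        assert "t" in fit.retained_terms
        assert "t3" not in fit.retained_terms

    def test_pure_noise_drops_everything(self, times):
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(times))
        fit = backward_stepwise(y, times)
        assert fit.is_intercept_only
        assert fit.r_squared == pytest.approx(0.0)

    def test_alpha_one_retains_full_model(self, times):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(times))
        fit = backward_stepwise(y, times, alpha=1.0)
        assert set(fit.retained_terms) == {"t", "t2", "t3"}

    def test_stepwise_never_increases_r2(self, times):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(size=len(times))
            full = fit_polynomial_timecourse(y, times)
            red = backward_stepwise(y, times)
            assert red.r_squared <= full.r_squared + 1e-12


class TestBenjaminiHochberg:
    def _step_up_oracle(self, p):
        # direct step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j) / j)
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out

    def test_textbook_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        assert np.allclose(benjamini_hochberg(ps), self._step_up_oracle(ps))


class TestSelection:
    def _planted(self, seed, n_sig=20, n_null=180, snr=3.0):
        metas = study_design()
        t = np.array([m.stage_code for m in metas], dtype=float)
        tc = t - t.mean()
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n_sig + n_null, len(t)))
        for i in range(n_sig):
            beta = rng.standard_normal(3)
            sig = beta[0] * tc + beta[1] * tc**2 + beta[2] * tc**3
            sig -= sig.mean()
            if sig.std() < 1e-9:
                sig = tc.copy()
            vals[i] += snr * sig / sig.std()
        return matrix_from_values(vals, metas), {f"f{i}" for i in range(n_sig)}

    def test_planted_signals_recovered_with_low_fdp(self):
        mat, truth = self._planted(seed=11)
        res = select_dynamic_features(mat)
        sel = set(res.dynamic_features)
        assert len(sel & truth) >= 18
        fdp = len(sel - truth) / max(len(sel), 1)
        assert fdp <= 0.10

    def test_all_null_selects_nearly_nothing(self):
        metas = study_design()
        rng = np.random.default_rng(3)
        mat = matrix_from_values(rng.standard_normal((300, len(metas))), metas)
        res = select_dynamic_features(mat)
        assert res.n_dynamic <= 3

    def test_empty_input_gives_empty_result(self):
        metas = study_design()
        mat = matrix_from_values(np.empty((0, len(metas))), metas, features=[])
        res = select_dynamic_features(mat)
        assert len(res.table) == 0 and res.n_dynamic == 0

    def test_threshold_monotonicity(self):
        mat, _ = self._planted(seed=21)
        loose = set(select_dynamic_features(mat, fdr=0.05, r2_min=0.5).dynamic_features)
        tight_fdr = set(select_dynamic_features(mat, fdr=0.01, r2_min=0.5).dynamic_features)
        tight_r2 = set(select_dynamic_features(mat, fdr=0.05, r2_min=0.8).dynamic_features)
        assert tight_fdr <= loose
        assert tight_r2 <= loose

    def test_model_front_end_matches_function(self):
        mat, _ = self._planted(seed=31, n_sig=5, n_null=20)
        a = DynamicFeatureModel(mat).fit()
        b = select_dynamic_features(mat)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert "dynamic features" in a.summary()

    def test_constant_feature_flagged_not_selected(self):
        metas = study_design()
        vals = np.vstack([np.ones(len(metas)), np.random.default_rng(0).normal(size=len(metas))])
        mat = matrix_from_values(vals, metas)
        res = select_dynamic_features(mat)
        assert not res.table.loc["f0", "testable"]
        assert not res.table.loc["f0", "is_dynamic"]


class TestHierarchical:
    def _profiles(self, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 7)
        rows = [t + rng.normal(0, 0.05, 7) for _ in range(n_per)]
        rows += [-t + rng.normal(0, 0.05, 7) for _ in range(n_per)]
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(2 * n_per)])

    def test_antipodal_archetypes_separate_perfectly(self):
        prof = self._profiles()
        res = hierarchical_cluster_profiles(prof, k=2)
        labels = res.assignments.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_k_one_single_cluster(self):
        res = hierarchical_cluster_profiles(self._profiles(), k=1)
        assert res.assignments.nunique() == 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster_profiles(self._profiles(n_per=2), k=10)

    def test_duplicated_rows_co_cluster(self):
        prof = self._profiles()
        prof.loc["dup"] = prof.loc["f0"]
        res = hierarchical_cluster_profiles(prof, k=2)
        assert res.assignments["dup"] == res.assignments["f0"]

    def test_feature_order_invariance(self):
        prof = self._profiles(seed=4)
        res1 = hierarchical_cluster_profiles(prof, k=2)
        shuffled = prof.sample(frac=1.0, random_state=9)
        res2 = hierarchical_cluster_profiles(shuffled, k=2)
        a = res1.assignments
        b = res2.assignments.loc[a.index]
        # same partition up to label names
        assert (pd.crosstab(a, b).to_numpy() > 0).sum() == 2


class TestFuzzyCMeans:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.1, size=(15, 5))
        b = rng.normal(5, 0.1, size=(15, 5))
        return pd.DataFrame(np.vstack([a, b]), index=[f"f{i}" for i in range(30)])

    def test_membership_rows_sum_to_one(self):
        res = fuzzy_cmeans(self._blobs(), c=3, seed=1)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_blobs_give_confident_memberships(self):
        res = fuzzy_cmeans(self._blobs(), c=2, seed=0)
        assert (res.membership.max(axis=1) > 0.9).all()

    def test_identical_points_identical_memberships(self):
        prof = self._blobs()
        prof.loc["dup"] = prof.loc["f0"]
        res = fuzzy_cmeans(prof, c=2, seed=0)
        assert np.allclose(res.membership.loc["dup"], res.membership.loc["f0"])

    def test_objective_non_increasing(self):
        res = fuzzy_cmeans(self._blobs(seed=2), c=2, seed=3)
        trace = np.asarray(res.params["objective_trace"])
        assert (np.diff(trace) <= 1e-9).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(self._blobs(), c=1)
        with pytest.raises(ValueError):
            fuzzy_cmeans(self._blobs(), c=2, m=1.0)
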
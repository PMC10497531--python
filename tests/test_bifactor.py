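"""ML bifactor engine: covariance algebra, discrepancy, gradient, fit indices."""

import numpy as np
import pytest

import darkcore as dc
from darkcore.bifactor import (
    ModelSpec,
    ParameterVector,
    ScaleMap,
    fit_indices,
    fml_gradient,
    implied_sigma,
    population_parameters,
)


def random_pd(rng, p):
    A = rng.standard_normal((p + 3, p))
    return A.T @ A / (p + 3) + 0.1 * np.eye(p)


class TestSampleCovariance:
    def test_hand_computed_biased_denominator(self):
        S = dc.sample_covariance(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(S, [[1.0, 1.0], [1.0, 1.0]])

    def test_exact_symmetry(self):
        rng = np.random.default_rng(4)
        S = dc.sample_covariance(rng.standard_normal((40, 7)))
        assert (S == S.T).all()

    def test_constant_column_names_item(self, small_pop):
        X = dc.generate(small_pop, 30, seed=2, likert=False)
        X.iloc[:, 2] = 1.0
        with pytest.raises(ValueError, match=X.columns[2]):
            dc.sample_covariance(X)


class TestImpliedSigma:
    @pytest.fixture
    def null_params(self, p6_spec):
        p, T = p6_spec.p, p6_spec.T
        x = np.concatenate([np.zeros(p - 1 + p - T), np.ones(p), np.ones(T + 1)])
        return ParameterVector.from_free(x, p6_spec)

    def test_marker_diagonal_bookkeeping(self, p6_spec, null_params):
        # item 0 is marker for both the general and its scale's factor
        sigma = implied_sigma(null_params, p6_spec)
        assert sigma[0, 0] == pytest.approx(1.0 * 1 + 1.0 * 1 + 1.0)

    def test_cross_scale_elements_via_general_only(self, p6_spec):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(-1, 1, 9), rng.uniform(0.5, 1.5, 9)])
        params = ParameterVector.from_free(x, p6_spec)
        sigma = implied_sigma(params, p6_spec)
        i, j = 1, 4  # items in different scales
        assert sigma[i, j] == pytest.approx(params.lam_g[i] * params.psi[0] * params.lam_g[j])
        assert (sigma == sigma.T).all()


class TestFml:
    def test_zero_at_saturation(self):
        rng = np.random.default_rng(1)
        S = random_pd(rng, 5)
        assert dc.fml(S, S.copy()) == 0.0

    def test_scalar_arithmetic_case(self):
        S = np.eye(2)
        Sigma = 2.0 * np.eye(2)
        assert dc.fml(S, Sigma) == pytest.approx(2 * np.log(2.0) + 1.0 - 2.0, abs=1e-12)

    def test_nonnegative_divergence(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            p = rng.integers(2, 7)
            assert dc.fml(random_pd(rng, p), random_pd(rng, p)) >= 0.0

    def test_singular_sigma_returns_sentinel_inf(self):
        S = np.eye(2)
        assert dc.fml(S, np.ones((2, 2))) == np.inf

    def test_singular_sample_raises(self):
        with pytest.raises(ValueError, match="singular"):
            dc.fml(np.ones((2, 2)), np.eye(2))


class TestDegreesOfFreedom:
    def test_full_16_scale_model(self, default_pop):
        spec = ModelSpec(ScaleMap.from_population(default_pop))
        assert spec.n_free_parameters == 453
        assert dc.degrees_of_freedom(spec) == 11_023

    def test_small_hand_count(self, p6_spec):
        # 21 moments - 18 free parameters
        assert dc.degrees_of_freedom(p6_spec) == 3

    def test_df_identity_matches_free_vector_length(self, small_run):
        spec = small_run["spec"]
        x = small_run["fit"].params.to_free(spec)
        assert dc.degrees_of_freedom(spec) == spec.p * (spec.p + 1) // 2 - x.size


class TestGradient:
    def test_matches_central_finite_differences(self, p6_spec):
        rng = np.random.default_rng(3)
        S = random_pd(rng, 6)
        h = 1e-6
        for _ in range(50):
            x = np.concatenate([rng.uniform(-1, 1, 9), rng.uniform(0.3, 1.5, 9)])
            params = ParameterVector.from_free(x, p6_spec)
            g = fml_gradient(params, p6_spec, S)
            for i in rng.choice(x.size, size=6, replace=False):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd = (
                    dc.fml(S, implied_sigma(ParameterVector.from_free(xp, p6_spec), p6_spec))
                    - dc.fml(S, implied_sigma(ParameterVector.from_free(xm, p6_spec), p6_spec))
                ) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def test_self_consistency_on_population_covariance(self, small_pop):
        """Fitting the exact population covariance must recover the generating
        parameters (in the marker metric) essentially perfectly."""
        spec = ModelSpec(ScaleMap.from_population(small_pop))
        theta_star = population_parameters(small_pop, spec)
        res = dc.fit(dc.implied_covariance(small_pop), 1000, spec)
        assert res.converged
        assert res.f_ml < 1e-8
        for a, b in [
            (res.params.lam_g, theta_star.lam_g),
            (res.params.lam_s, theta_star.lam_s),
            (res.params.theta, theta_star.theta),
            (res.params.psi, theta_star.psi),
        ]:
            assert np.abs(a - b).max() < 1e-3

    def test_scale_invariance_of_discrepancy(self, small_run):
        """Multiplying all items of one scale by 2 rescales loadings and
        variances but leaves the ML discrepancy (and chi-square) unchanged."""
        X = small_run["X"].copy()
        idx = small_run["smap"].scale_indices("s2")
        X.iloc[:, idx] = X.iloc[:, idx] * 2.0
        res = dc.fit(dc.sample_covariance(X), X.shape[0], small_run["spec"])
        assert res.f_ml == pytest.approx(small_run["fit"].f_ml, abs=1e-6)
        assert res.chi_square == pytest.approx(small_run["fit"].chi_square, abs=1e-3)

    def test_item_order_invariance(self, small_pop, small_run):
        """Reordering the scale blocks (which also changes the marker items)
        must not change the attained discrepancy."""
        X = small_run["X"]
        order = ["s3", "s1", "s4", "s2"]
        cols = [i for s in order for i in X.columns if i.startswith(s + ".")]
        Xp = X.loc[:, cols]
        smap = ScaleMap(
            item_ids=tuple(cols), item_scale=tuple(c.split(".")[0] for c in cols)
        )
        res = dc.fit(dc.sample_covariance(Xp), Xp.shape[0], ModelSpec(smap))
        assert res.f_ml == pytest.approx(small_run["fit"].f_ml, abs=1e-6)

    def test_chi2_convention_option(self, small_run):
        X = small_run["X"]
        res = dc.fit(
            dc.sample_covariance(X), X.shape[0], small_run["spec"], dc.FitOptions(chi2_n="n-1")
        )
        assert res.chi_square == pytest.approx(
            small_run["fit"].chi_square * (X.shape[0] - 1) / X.shape[0], rel=1e-6
        )

    def test_json_round_trip(self, small_run):
        from darkcore.bifactor import BifactorFit

        back = BifactorFit.from_json(small_run["fit"].to_json())
        assert back.df == small_run["fit"].df
        assert back.f_ml == pytest.approx(small_run["fit"].f_ml)
        assert np.allclose(back.params.lam_g, small_run["fit"].params.lam_g)

    def test_dimension_mismatch_raises(self, p6_spec):
        with pytest.raises(ValueError, match="spec expects"):
            dc.fit(np.eye(4), 100, p6_spec)


class TestFitIndices:
    def test_published_statistics_reproduce_rmsea(self):
        """chi2(11,023) = 35,211 at N = 1,676 gives RMSEA 0.036, CI [0.036; 0.037]."""
        rmsea, ci, srmr, p = fit_indices(35_211, 11_023, 1_676, np.eye(2), np.eye(2))
        assert round(rmsea, 3) == 0.036
        assert round(ci[0], 3) == 0.036
        assert round(ci[1], 3) == 0.037
        assert ci[0] <= rmsea <= ci[1]
        assert p < 0.001

    def test_zero_noncentrality(self):
        rmsea, ci, srmr, _ = fit_indices(100.0, 100, 500, np.eye(2), np.eye(2))
        assert rmsea == 0.0
        assert ci[0] == 0.0

    def test_srmr_zero_at_saturation(self):
        rng = np.random.default_rng(5)
        S = random_pd(rng, 4)
        _, _, srmr, _ = fit_indices(50.0, 10, 100, S, S.copy())
        assert srmr == 0.0

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError, match="df"):
            fit_indices(10.0, 0, 100, np.eye(2), np.eye(2))
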
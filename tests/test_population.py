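"""Synthetic bifactor population: structure, generation and its oracle covariance."""

import numpy as np
import pytest

import darkcore as dc
from darkcore.population import (
    BASE_THRESHOLDS,
    PopulationModel,
    ScaleSpec,
    expected_item_means,
    population_ecv,
)

EXPECTED_COUNTS = [13, 12, 9, 6, 14, 7, 9, 8, 9, 6, 8, 9, 10, 4, 17, 10]


class TestDefaultPopulation:
    def test_dimensions(self, default_pop):
        assert [s.n_items for s in default_pop.scales] == EXPECTED_COUNTS
        assert default_pop.n_items == 151
        assert default_pop.n_scales == 16
        # one general + 16 specific factors
        assert default_pop.loading_matrix().shape == (151, 17)

    def test_implied_covariance_is_spd_with_unit_diagonal(self, default_pop):
        sigma = dc.implied_covariance(default_pop)
        assert np.allclose(sigma, sigma.T)
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_floor_effect_scale_mean(self, default_pop):
        """The Sadism-like scale's strong threshold shift puts its observed
        mean near 1.44, far below every other scale."""
        X = dc.generate(default_pop, 10_000, seed=123, likert=True)
        by_scale = X.T.groupby(np.array(default_pop.item_scale)).mean().mean(axis=1)
        assert 1.3 <= by_scale["sadism"] <= 1.6
        others = by_scale.drop("sadism")
        assert others.between(1.75, 2.94).all()

    def test_saturation_gradient_in_population_ecv(self, default_pop):
        ecv = population_ecv(default_pop)
        assert ecv["frustralia"] > ecv["narcissism_sd3"]
        assert ecv["machiavellianism"] > ecv["entitlement"]
        assert ecv["crudelia"] > ecv["greed"]


class TestImpliedCovariance:
    def test_one_factor_closed_form(self):
        model = PopulationModel(
            scales=(
                ScaleSpec(
                    name="s",
                    general_loadings=np.array([0.6, 0.6]),
                    specific_loadings=np.array([0.0, 0.0]),
                    thresholds=np.tile(BASE_THRESHOLDS, (2, 1)),
                ),
            )
        )
        assert np.allclose(dc.implied_covariance(model), [[1.0, 0.36], [0.36, 1.0]])

    def test_cross_scale_covariance_is_general_only(self, default_pop):
        sigma = dc.implied_covariance(default_pop)
        lam_g = default_pop.general_loadings
        # first item of scale 1 vs first item of scale 2
        j = default_pop.scales[0].n_items
        assert sigma[0, j] == pytest.approx(lam_g[0] * lam_g[j], abs=1e-12)


class TestGenerate:
    def test_reproducible_bitwise(self, default_pop):
        a = dc.generate(default_pop, 50, seed=7)
        b = dc.generate(default_pop, 50, seed=7)
        assert (a.values == b.values).all()
        c = dc.generate(default_pop, 50, seed=8)
        assert (a.values != c.values).any()

    def test_likert_range_and_shape(self, default_pop):
        X = dc.generate(default_pop, 1676, seed=1, likert=True)
        assert X.shape == (1676, 151)
        assert X.values.min() >= 1 and X.values.max() <= 5
        assert X.values.dtype.kind == "i"

    def test_minimal_n_continuous(self, small_pop):
        X = dc.generate(small_pop, 2, seed=7, likert=False)
        assert X.shape == (2, small_pop.n_items)
        assert X.values.dtype.kind == "f"

    def test_sample_covariance_converges_to_implied(self, default_pop):
        """Law of large numbers: at n = 50,000 the continuous sample
        covariance matches the closed-form population covariance."""
        X = dc.generate(default_pop, 50_000, seed=3, likert=False)
        S = dc.sample_covariance(X)
        assert np.abs(S - dc.implied_covariance(default_pop)).max() < 0.02

    def test_rejects_invalid_inputs(self, default_pop):
        with pytest.raises(ValueError, match="n must be"):
            dc.generate(default_pop, 1, seed=0)
        with pytest.raises(ValueError, match="communality"):
            ScaleSpec(
                name="bad",
                general_loadings=np.array([0.9, 0.9]),
                specific_loadings=np.array([0.6, 0.6]),
                thresholds=np.tile(BASE_THRESHOLDS, (2, 1)),
            )
        with pytest.raises(ValueError, match="increasing"):
            ScaleSpec(
                name="bad",
                general_loadings=np.array([0.5, 0.5]),
                specific_loadings=np.array([0.3, 0.3]),
                thresholds=np.array([[0.0, 0.0, 1.0, 2.0]] * 2),
            )

    @pytest.mark.parametrize("delta", [0.3, 0.8, 1.5])
    def test_raising_thresholds_never_raises_observed_means(self, delta):
        """Discretization monotonicity: shifting all cut-points upward can
        only move responses toward lower categories."""
        base = dc.make_gradient_population(n_scales=3, items_per_scale=3)
        shifted = PopulationModel(
            scales=tuple(
                ScaleSpec(
                    name=s.name,
                    general_loadings=s.general_loadings,
                    specific_loadings=s.specific_loadings,
                    thresholds=s.thresholds + delta,
                )
                for s in base.scales
            )
        )
        a = dc.generate(base, 400, seed=11, likert=True)
        b = dc.generate(shifted, 400, seed=11, likert=True)
        assert (b.mean(axis=0) <= a.mean(axis=0) + 1e-12).all()
        # closed-form expectations agree with the ordering
        assert (expected_item_means(shifted) <= expected_item_means(base)).all()
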
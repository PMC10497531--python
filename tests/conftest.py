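import numpy as np
import pytest

import darkcore as dc
from darkcore.bifactor import ModelSpec, ScaleMap
from darkcore.population import BASE_THRESHOLDS, PopulationModel, ScaleSpec


@pytest.fixture(scope="session")
def default_pop():
    return dc.make_default_population()


def _uniform_population(n_scales, items_per_scale, lam_g=0.7, lam_s=0.35):
    scales = [
        ScaleSpec(
            name=f"s{t + 1}",
            general_loadings=np.full(items_per_scale, lam_g),
            specific_loadings=np.full(items_per_scale, lam_s),
            thresholds=np.tile(BASE_THRESHOLDS, (items_per_scale, 1)),
        )
        for t in range(n_scales)
    ]
    return PopulationModel(scales=tuple(scales))


@pytest.fixture(scope="session")
def small_pop():
    """4 scales x 3 items with substantial general loadings."""
    return _uniform_population(4, 3)


@pytest.fixture(scope="session")
def small_run(small_pop):
    """Continuous data, full fit and full-model D scores on the small model."""
    X, F = dc.generate(small_pop, 600, seed=20, likert=False, return_factors=True)
    smap = ScaleMap.from_population(small_pop)
    spec = ModelSpec(smap)
    fit = dc.fit(dc.sample_covariance(X), X.shape[0], spec)
    scores = dc.score_general_factor(X, fit, spec)
    return {"X": X, "F": F, "smap": smap, "spec": spec, "fit": fit, "scores": scores}


@pytest.fixture(scope="session")
def p6_spec():
    """Tiny 2-scale spec used for gradient and algebra checks."""
    return ModelSpec(ScaleMap(item_ids=tuple("abcdef"), item_scale=("s1",) * 3 + ("s2",) * 3))
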
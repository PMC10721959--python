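import numpy as np
import pytest

from fireabund.model_core import ModelData
from fireabund.preprocessing import ModelFlags


@pytest.fixture
def rng():
    return np.random.default_rng(20160606)


@pytest.fixture
def small_model_data(rng):
    """3 species x 4 plots x 2 visits on 2 sites, random design entries."""
    n_obs, p, S = 8, 4, 3
    X = np.column_stack([
        np.ones(n_obs),
        rng.normal(size=(n_obs, p - 1)),
    ])
    y = rng.integers(0, 12, size=(S, n_obs))
    site_index = np.repeat([0, 1], n_obs // 2)
    return ModelData(
        X=X, y=y, site_index=site_index,
        plot_index=np.repeat(np.arange(4), 2),
        n_sites=2, species_ids=[f"sp{i}" for i in range(S)],
        column_names=["intercept", "a", "b", "c"],
        flags=ModelFlags(), site_ids=["s1", "s2"],
    )
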
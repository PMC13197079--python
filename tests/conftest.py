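import numpy as np
import pytest

from traitgroups import ErrorModel, TraitTable
from traitgroups.synthetic import SyntheticSpec, generate_case_study_miniature, generate_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Tiny 6-species, 3-trait table with two taxa."""
    values = np.array([
        [1.0, 2.0, 3.0],
        [1.1, 2.1, 3.1],
        [4.0, 5.0, 6.0],
        [4.1, 5.1, 6.1],
        [0.0, 0.5, 1.0],
        [0.1, 0.6, 1.1],
    ])
    return TraitTable(
        species_ids=[f"sp{i}" for i in range(6)],
        trait_names=["height", "leaf_area", "wood_density"],
        values=values,
        taxon=["angiosperm"] * 4 + ["gymnosperm"] * 2,
    )


@pytest.fixture
def zero_error_model(small_table):
    """Pools of {0} for every (taxon, trait): resamples reproduce X."""
    pools = {
        (t, j): [0.0]
        for t in ("angiosperm", "gymnosperm")
        for j in small_table.trait_names
    }
    return ErrorModel.from_pools(pools)


@pytest.fixture(scope="session")
def four_group_mixture():
    """Well-separated 4-group mixture with moderate error pools."""
    spec = SyntheticSpec(n_species=400, n_traits=6, n_groups=4,
                         separation=8.0, covariance="correlated", rho=0.4,
                         error_mae=0.15, seed=7)
    return generate_mixture(spec)


@pytest.fixture(scope="session")
def miniature():
    """Session-cached 1,500-species, 18-trait case-study miniature."""
    return generate_case_study_miniature(seed=0)
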
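import warnings

import numpy as np
import pytest

from catmap.linkage import LinkageMapModel, MapConfig
from catmap.simulate import (
    PedigreeSpec,
    TrueMapConfig,
    simulate_families,
    simulate_genome,
    simulate_variant_pool,
)

# the study conditions: four full-sib families sharing one sire, three
# chromosomes of 80-120 cM with 200 evenly spaced markers each, 1%
# genotyping error, 2% missingness, female map 1.4x the male map
STUDY_SEED = 5
STUDY_LENGTHS = (100.0, 80.0, 120.0)


@pytest.fixture(scope="session")
def study():
    cfg = TrueMapConfig.regular(
        3,
        list(STUDY_LENGTHS),
        200,
        genotyping_error_rate=0.01,
        missing_rate=0.02,
        female_scale=1.4,
    )
    peds, matrix, truth = simulate_families(
        cfg, PedigreeSpec((120, 119, 120, 119)), seed=STUDY_SEED
    )
    return {"pedigrees": peds, "matrix": matrix, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def study_fit(study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LinkageMapModel(
            study["matrix"], study["pedigrees"], MapConfig(seed=17)
        )
        return model.fit()


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(5, 120_000, genic_fraction=0.3, repeat_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_genome):
    return simulate_variant_pool(small_genome, density_per_kb=1.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
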
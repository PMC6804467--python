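import numpy as np
import pandas as pd
import pytest

from synlink import (
    ArtifactSpec,
    AssayDesign,
    DrugParams,
    GeneticMap,
    simulate_genotypes,
    simulate_pedigrees,
)


@pytest.fixture(scope="session")
def trio_pedigree():
    return simulate_pedigrees(45, children_per_family=1, seed=11)


@pytest.fixture(scope="session")
def small_pedigree():
    """12 nuclear families with 2-4 children."""
    return simulate_pedigrees(12, (2, 4), seed=7)


@pytest.fixture(scope="session")
def small_map():
    return GeneticMap.uniform(n_chromosomes=2, n_markers_per_chromosome=20, spacing_cM=2.0)


@pytest.fixture(scope="session")
def small_genotypes(small_pedigree, small_map):
    return simulate_genotypes(small_pedigree, small_map, seed=13)


@pytest.fixture(scope="session")
def default_design():
    return AssayDesign.default()


@pytest.fixture(scope="session")
def default_drug_params():
    return {
        "drugA": DrugParams(dm=4.0, m=1.5, cv=0.2),
        "drugB": DrugParams(dm=1.0, m=2.0, cv=0.2),
    }


@pytest.fixture
def clean_artifacts():
    return ArtifactSpec()


@pytest.fixture(scope="session")
def constant_latent():
    def make(lines, ci):
        return pd.Series(np.log(ci), index=list(lines))

    return make
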
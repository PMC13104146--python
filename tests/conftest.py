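import numpy as np
import pytest

from stemniche.metacell import MetacellConfig
from stemniche.network import NetworkConfig
from stemniche.pipeline import derive_csc_signature, map_tumor_boundary
from stemniche.sim import (
    ScSimConfig,
    SpatialSimConfig,
    reference_profiles_from_cohort,
    simulate_sc_cohort,
    simulate_visium_section,
)
from stemniche.sim.spatial import gene_positions

# Desk-scale settings: the bootstrap count, neighborhood size and minimum
# metacell size are reduced from the full-scale defaults (500/100/50, sized
# for ~50k cells) to fit a 2,000-cell cohort and the CI budget.
TEST_METACELL_CONFIG = dict(n_boot=30, knn_k=60, min_size=40, resolution=2.0, seed=0)
TEST_NETWORK_CONFIG = dict(n_top_genes=1500)


@pytest.fixture(scope="session")
def sc_cohort():
    return simulate_sc_cohort(ScSimConfig(seed=1))


@pytest.fixture(scope="session")
def signature_run(sc_cohort):
    matrix, truth = sc_cohort
    return derive_csc_signature(
        matrix,
        truth.malignant_mask,
        metacell_config=MetacellConfig(**TEST_METACELL_CONFIG),
        network_config=NetworkConfig(**TEST_NETWORK_CONFIG),
    )


@pytest.fixture(scope="session")
def reference_profiles(sc_cohort):
    matrix, _ = sc_cohort
    return reference_profiles_from_cohort(matrix)


@pytest.fixture(scope="session")
def spatial_section(reference_profiles):
    return simulate_visium_section(SpatialSimConfig(seed=3), reference_profiles)


@pytest.fixture(scope="session")
def spatial_run(spatial_section):
    grid, _ = spatial_section
    annotation = gene_positions(grid.matrix.genes)
    return map_tumor_boundary(grid, annotation, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
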
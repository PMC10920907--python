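"""Shared fixtures: all test data come from the synthetic generator."""

import numpy as np
import pytest

from overyield import synth
from overyield.io_model import build_monoculture_reference


@pytest.fixture(scope="session")
def pool():
    """Default 200-species pool, complete traits, with ground truth."""
    matrix, truth = synth.make_species_pool(200, seed=11, missingness=0.0)
    return matrix, truth


@pytest.fixture(scope="session")
def pool_gappy():
    """Species pool with 15% missing trait cells."""
    matrix, truth = synth.make_species_pool(200, seed=11, missingness=0.15)
    return matrix, truth


@pytest.fixture(scope="session")
def grassland_small():
    """Small grassland experiment: 4 sites, 8 species each, 6 years."""
    matrix, truth = synth.make_species_pool(40, seed=3, missingness=0.0)
    prod, comp = synth.simulate_grassland(
        truth, n_sites=4, richness_levels=(1, 2, 4, 8), plots_per_richness=2,
        mono_reps=2, n_years=6, species_per_site=8, seed=3,
    )
    return prod, comp, truth


@pytest.fixture(scope="session")
def grassland_metrics(grassland_small):
    from overyield.metrics import compute_overyielding

    prod, comp, truth = grassland_small
    reference, _ = build_monoculture_reference(prod, comp)
    st, ct, summary = compute_overyielding(prod, comp, reference)
    return st, ct, summary, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
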
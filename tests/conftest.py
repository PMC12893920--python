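import numpy as np
import pytest

from axistk.synthetic import (
    generate_species_pair,
    generate_tube_organ,
)


@pytest.fixture(scope="session")
def tube_bundle():
    """Small curved tube with 30% gradient genes; shared across tests."""
    return generate_tube_organ(n_units=300, n_genes=60, frac_gradient=0.3, seed=11)


@pytest.fixture(scope="session")
def species_pair():
    """Small two-species pair with 3 shared populations."""
    return generate_species_pair(
        n_cells_per_species=400, n_populations=3, orth_frac=0.8, n_genes=200, seed=21
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
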
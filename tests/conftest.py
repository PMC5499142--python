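import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scafmap.matrix import GenotypeMatrix
from scafmap.simdata import GenomeConfig, simulate_cross, simulate_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170519)


@pytest.fixture(scope="session")
def small_cross():
    """A 3-chromosome cross, reused across tests that need real structure."""
    cfg = GenomeConfig(n_chromosomes=3, scaffolds_per_chromosome=20)
    genome, truth = simulate_genome(cfg, 42)
    family, matrix, truth = simulate_cross(
        genome, truth, n_offspring=94, marker_density=60.0, cm_per_mb=40.0, seed=43
    )
    return genome, truth, family, matrix


def make_matrix(genotypes, qualities=None, scaffolds=None, positions=None, is_indel=None):
    """Small helper to build a GenotypeMatrix from plain arrays."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_mark, n_samp = g.shape
    q = (
        np.asarray(qualities, dtype=np.int16)
        if qualities is not None
        else np.full(g.shape, 60, dtype=np.int16)
    )
    scaffolds = scaffolds if scaffolds is not None else ["S1"] * n_mark
    positions = positions if positions is not None else list(range(1, n_mark + 1))
    is_indel = is_indel if is_indel is not None else [False] * n_mark
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_mark)],
            "scaffold_id": scaffolds,
            "position": positions,
            "ref": ["A"] * n_mark,
            "alt": ["T"] * n_mark,
            "is_indel": is_indel,
        }
    )
    samples = [f"s{j}" for j in range(n_samp)]
    return GenotypeMatrix(markers, samples, g, q)


@pytest.fixture
def matrix_factory():
    return make_matrix
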
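import numpy as np
import pytest

import fconnet as fc


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdos–Renyi adjacency as a plain 0/1 array."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, k=1)
    return a | a.T


@pytest.fixture(scope="session")
def atlas24():
    return fc.make_atlas(24)


@pytest.fixture(scope="session")
def micro_cohort(atlas24):
    """Three groups of 6 subjects, 24 ROIs, 80 timepoints."""
    design = fc.default_design(atlas24, n_subjects=6, n_timepoints=80, seed=7)
    return fc.generate_cohort(atlas24, design)


@pytest.fixture(scope="session")
def micro_matrices(micro_cohort):
    return [fc.pearson_matrix(ts) for ts in micro_cohort]
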
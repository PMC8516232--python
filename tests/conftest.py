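import numpy as np
import pytest

import kmerscape as km


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def small_clade():
    """A 16-genome clade (2 superkingdoms x 2 genera x 2 species x 2 strains)
    of 20 kbp genomes, with taxonomy and true tree; session-scoped because
    several modules test against the same ground truth."""
    spec = km.CladeSpec(root_length=20_000, seed=77)
    records, taxonomy, truth = km.simulate_clade(spec)
    return spec, records, taxonomy, truth


@pytest.fixture(scope="session")
def small_clade_sets(small_clade):
    _, records, _, _ = small_clade
    return [(r.genome_id, km.extract_canonical_kmers(r, 21)) for r in records]


@pytest.fixture(scope="session")
def small_clade_similarity(small_clade_sets):
    return km.pairwise_matrix(small_clade_sets)
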
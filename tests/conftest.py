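import itertools

import numpy as np
import pytest

from sdm_phylo import (
    SyntheticTreeSpec,
    build_matrix,
    evolve_along_tree,
    iterative_align,
    make_template,
    pair_record,
)


@pytest.fixture(scope="session")
def template160():
    return make_template(160, 7)


@pytest.fixture(scope="session")
def family8_spec():
    return SyntheticTreeSpec(seed=11)


@pytest.fixture(scope="session")
def family8(family8_spec):
    return evolve_along_tree(family8_spec)


@pytest.fixture(scope="session")
def family8_alignments(family8):
    labels = list(family8)
    return {
        (a, b): iterative_align(family8[a], family8[b])
        for a, b in itertools.combinations(labels, 2)
    }


@pytest.fixture(scope="session")
def family8_matrix(family8, family8_alignments):
    labels = list(family8)
    records = [
        pair_record(aln, family8[a], family8[b])
        for (a, b), aln in family8_alignments.items()
    ]
    matrix, table = build_matrix(records, labels)
    return matrix, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
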
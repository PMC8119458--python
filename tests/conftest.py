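"""Shared fixtures: the synthetic corpus and a full table set.

Building tables over the corpus is the expensive step, so it is done
once per session with a reduced sphere codebook (the codebook size does
not affect table normalisation or any scale targets).
"""

import numpy as np
import pytest

from briq import fixtures as fx
from briq import tables as tbl


TEST_CODEBOOK_SIZE = 300


@pytest.fixture(scope="session")
def corpus():
    structures, annotations = fx.fixture_corpus(seed=0)
    return structures, annotations


@pytest.fixture(scope="session")
def table_set(corpus):
    structures, annotations = corpus
    return tbl.build_all_tables(structures, annotations, seed=0,
                                codebook_size=TEST_CODEBOOK_SIZE)


@pytest.fixture(scope="session")
def tetraloop():
    return fx.tetraloop()


@pytest.fixture(scope="session")
def tetraloop_annotation():
    return fx.tetraloop_annotation()


@pytest.fixture(scope="session")
def gc_helix():
    return fx.ideal_helix("GCGCGCGC")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
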
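import numpy as np
import pytest

import topicgrad as tg


def raw_input(matrix: tg.CountMatrix) -> tg.LdaInput:
    """Feed a count matrix to the sampler directly (counts as token multiplicities)."""
    return tg.LdaInput(
        matrix=matrix.counts,
        gene_names=matrix.gene_names,
        cell_barcodes=matrix.cell_barcodes,
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-topic corpus shared by unit tests (not the reference scale)."""
    return tg.generate_lda_corpus(
        n_cells=120, n_genes=60, n_topics=3, depth=200, seed=7
    )


@pytest.fixture(scope="session")
def small_model(small_planted):
    matrix, _ = small_planted
    return tg.fit_lda(raw_input(matrix), 3, iterations=300, burn_in=150, seed=7)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 cells with hand-checkable sums."""
    return tg.CountMatrix(
        counts=np.array([[1, 0], [2, 5], [0, 3]]),
        gene_names=np.array(["GA", "GB", "GC"], dtype=object),
        cell_barcodes=np.array(["c1", "c2"], dtype=object),
    )
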
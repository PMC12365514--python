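import numpy as np
import pytest

from ptmfusion.datatypes import AssociationMatrix, SimilarityMatrix


@pytest.fixture
def tiny_assoc():
    """6 proteins x 4 diseases with a fixed sparse pattern."""
    values = np.array(
        [
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ],
        dtype=float,
    )
    return AssociationMatrix(
        values, [f"p{i}" for i in range(6)], [f"d{j}" for j in range(4)]
    )


@pytest.fixture
def tiny_similarities(tiny_assoc):
    rng = np.random.default_rng(42)
    n_p, n_d = tiny_assoc.values.shape
    sp = rng.random((n_p, n_p))
    sp = 0.5 * (sp + sp.T)
    np.fill_diagonal(sp, 1.0)
    sd = rng.random((n_d, n_d))
    sd = 0.5 * (sd + sd.T)
    np.fill_diagonal(sd, 1.0)
    return (
        SimilarityMatrix(sp, tiny_assoc.protein_ids, "fused"),
        SimilarityMatrix(sd, tiny_assoc.disease_ids, "gip"),
    )
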
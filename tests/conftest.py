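import numpy as np
import pytest
import scipy.sparse as sp

from docthemes.corpus import build_matrix
from docthemes.synthetic import AUDIT_TOKENS, PlantedSpec, generate_ideal


def random_sparse_nonneg(rng, n_rows=None, n_cols=None, density=0.3, gap=0.02):
    """Random sparse non-negative matrix with an audited spectral gap.

    Regenerates until (s1 - s2)/s1 > gap. The default 0.02 is what the
    cosine-stability stopping rule (tol 1e-10) needs to land within
    ~4e-4 of the first singular vector: the residual error after the
    stop is about sqrt(2 tol)/(1 - (s2/s1)^2).
    """
    while True:
        r = n_rows or rng.integers(3, 21)
        c = n_cols or rng.integers(4, 31)
        rs = np.random.RandomState(int(rng.integers(2**31)))
        M = sp.random(r, c, density=density, random_state=rs, data_rvs=lambda k: np.abs(rs.randn(k))).tocsr()
        if M.nnz == 0:
            continue
        s = np.linalg.svd(M.toarray(), compute_uv=False)
        if len(s) > 1 and s[0] > 0 and (s[0] - s[1]) / s[0] > gap:
            return M
        if len(s) == 1 and s[0] > 0:
            return M


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ideal_corpus():
    """Small audited ideal-case corpus with its tf-idf matrix."""
    spec = PlantedSpec(n_blocks=3, block_sizes=30, block_vocab_size=40, noise_rate=0.05, rng_seed=11)
    docs, truth = generate_ideal(spec)
    matrix = build_matrix(docs, AUDIT_TOKENS)
    return docs, truth, matrix
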
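import numpy as np
import pytest

from eqtlcausal import ExpressionMatrix, GenotypeMatrix, encode_genotypes, supernormalize


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def triple(rng):
    """A moderately-sized supernormalized (E, A, B) triple with signal."""
    n = 60
    E = rng.integers(0, 3, n)
    while len(np.unique(E)) < 3:
        E = rng.integers(0, 3, n)
    A = supernormalize(rng.normal(size=n) + 0.6 * E)
    B = supernormalize(rng.normal(size=n) + 0.5 * A)
    return encode_genotypes(E), A, B


@pytest.fixture
def tiny_dataset(rng):
    """20 genes x 40 samples with each gene anchored to its own eQTL."""
    n_genes, n = 20, 40
    geno = rng.integers(0, 3, size=(n_genes, n))
    for i in range(n_genes):
        while len(np.unique(geno[i])) < 2:
            geno[i] = rng.integers(0, 3, n)
    expr = 0.8 * geno + rng.normal(size=(n_genes, n))
    # one planted chain: gene 0 -> gene 1
    expr[1] += 1.2 * expr[0]
    gene_ids = [f"G{i:02d}" for i in range(n_genes)]
    eqtl_ids = [f"E{i:02d}" for i in range(n_genes)]
    sample_ids = [f"S{j:02d}" for j in range(n)]
    expression = ExpressionMatrix(gene_ids, expr, sample_ids)
    genotypes = GenotypeMatrix(eqtl_ids, geno, sample_ids)
    pairs = list(zip(eqtl_ids, gene_ids))
    return expression, genotypes, pairs
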
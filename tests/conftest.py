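import numpy as np
import pytest

from braincoex.expression_io import ExpressionMatrix, GeneSet


def make_expression(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        gene_ids=np.array(gene_ids or [f"G{i}" for i in range(n_genes)], dtype=object),
        sample_ids=np.array(
            sample_ids or [f"S{j}" for j in range(n_samples)], dtype=object
        ),
        values=values,
    )


def make_set(name, genes, category="other") -> GeneSet:
    return GeneSet(name=name, genes=frozenset(genes), category=category)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr(rng):
    """10 genes x 20 samples of pure noise."""
    return make_expression(rng.standard_normal((10, 20)))
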
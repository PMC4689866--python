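import numpy as np
import pytest

import mybnet as m


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across read-only tests."""
    cfg = m.SyntheticConfig(seed=11)
    matrix, annotations, promoters, truth = m.generate_all(cfg)
    return cfg, matrix, annotations, promoters, truth


@pytest.fixture(scope="session")
def default_network(default_dataset):
    _, matrix, _, _, _ = default_dataset
    corr = m.pearson_all_pairs(matrix)
    return corr, m.build_network(corr, 0.85)


def random_correlation_matrix(n_genes: int, n_samples: int, seed: int) -> m.CorrelationMatrix:
    """Correlation matrix of iid Gaussian profiles (valid PSD structure)."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_genes, n_samples))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return m.CorrelationMatrix(gene_ids=genes, r_values=np.corrcoef(data),
                               n_samples=n_samples)
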
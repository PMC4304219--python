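import numpy as np
import pytest

from genemod import ExpressionMatrix, PlantedDesign, generate


def random_matrix(n_genes, n_samples, n_regulators, seed):
    """Normalized random matrix with the first n_regulators genes flagged."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=1, keepdims=True
    )
    flags = np.zeros(n_genes, dtype=bool)
    flags[:n_regulators] = True
    return ExpressionMatrix(
        gene_ids=tuple(f"g{i}" for i in range(n_genes)),
        sample_ids=tuple(f"s{j}" for j in range(n_samples)),
        values=values,
        regulator_flags=flags,
    )


@pytest.fixture
def small_matrix():
    return random_matrix(n_genes=20, n_samples=12, n_regulators=6, seed=42)


@pytest.fixture
def planted():
    design = PlantedDesign(
        n_regulators=20,
        n_modules=4,
        regulators_per_module=(1, 2),
        genes_per_module=(10, 10),
        n_background_genes=20,
        noise_sd=0.1,
        m_samples=80,
        seed=7,
    )
    return generate(design)
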
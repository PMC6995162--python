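import numpy as np
import pytest

from mirnorm import ExpressionTable, curate_dataset
from mirnorm.simulate import SimulationSpec, generate_dataset


def random_table(rng, n_genes=6, n_samples=6, groups=None, spread=2.0):
    """A dense random Cq table in a realistic cycle window."""
    cq = rng.uniform(18.0, 30.0, size=(n_genes, 1)) + rng.normal(
        0.0, spread, size=(n_genes, n_samples)
    )
    return ExpressionTable(
        gene_ids=[f"g{i:02d}" for i in range(n_genes)],
        sample_ids=[f"s{j:02d}" for j in range(n_samples)],
        cq=cq,
        groups=groups,
    )


def random_grouped_table(rng, n_genes=6, group_sizes=(3, 3)):
    n_samples = sum(group_sizes)
    labels = []
    for a, size in enumerate(group_sizes):
        labels.extend([f"G{a + 1}"] * size)
    return random_table(rng, n_genes=n_genes, n_samples=n_samples, groups=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_table(rng):
    return random_table(rng, n_genes=8, n_samples=6)


@pytest.fixture
def grouped_table(rng):
    return random_grouped_table(rng, n_genes=8, group_sizes=(4, 4))


@pytest.fixture
def planted_expr():
    """30-gene table with 3 planted low-noise reference genes, no groups."""
    raw, truth = generate_dataset(
        SimulationSpec(n_genes=30, n_samples=10, n_stable=3, seed=421)
    )
    return curate_dataset(raw).to_expression_table(), truth
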
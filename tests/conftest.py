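import numpy as np
import pytest

from metconnect.expression import ExpressionDataset
from metconnect.simulate import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Reduced study conditions for fast unit tests (structure, not power)."""
    return SimulationConfig(
        n_genes=400,
        n_normal=15,
        n_cancer=15,
        n_datasets=2,
        n_modules=3,
        module_size_range=(24, 30),
        n_cancer_modules=2,
        de_fraction=0.1,
        n_drugs=40,
        instances_per_drug=3,
        n_reversers=6,
        n_enzymes=40,
        n_planted_key_enzymes=6,
        partners_per_key=3,
        n_reactions=34,
        n_planted_candidates=4,
        missing_rate=0.02,
        seed=7,
    )


def make_dataset(
    values, dataset_id="toy", genes=None, samples=None, phenotype=None
) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = samples if samples is not None else [f"s{j}" for j in range(n_samples)]
    if phenotype is None:
        half = n_samples // 2
        phenotype = ["normal"] * half + ["cancer"] * (n_samples - half)
    return ExpressionDataset(dataset_id, genes, samples, values, phenotype)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(0)
    return make_dataset(rng.normal(8, 1, size=(20, 10)))
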
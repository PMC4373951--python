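import numpy as np
import pandas as pd
import pytest

from fibrosig.dataset import ExpressionDataset
from fibrosig.simulate import SimulationConfig, generate_expression


def make_dataset(values: np.ndarray, annot: dict[str, list[str]] | None = None,
                 genes=None, samples=None) -> ExpressionDataset:
    """Small helper: wrap a raw matrix into a valid dataset."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    base = {
        "patient": [f"p{j}" for j in range(n_samples)],
        "tissue": ["synovium"] * n_samples,
        "disease": ["RA"] * n_samples,
        "serum": ["low"] * n_samples,
    }
    if annot:
        base.update(annot)
    annotation = pd.DataFrame(base, index=pd.Index(samples, name="sample_id"))
    return ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples), annotation
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down generator config for fast unit tests."""
    return SimulationConfig(
        n_genes=400, n_site_genes=90, n_serum_genes=40, n_disease_genes=20,
        n_oa_synovium_genes=15, seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_expression(small_config)


@pytest.fixture(scope="session")
def default_data():
    """The full-size default generator output (shared; ~1 s to build)."""
    config = SimulationConfig()
    dataset, truth = generate_expression(config)
    return config, dataset, truth
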
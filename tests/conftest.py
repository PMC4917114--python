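import numpy as np
import pandas as pd
import pytest

from coexseed.datatypes import ExpressionDataset
from coexseed.synthetic import StudyConfig, generate_multi_platform_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_study():
    """A compact two-platform SI/C + one-platform SI/SIII study."""
    cfg = StudyConfig(
        n_platforms=3,
        samples_per_group=8,
        n_genes=120,
        module_sizes=(25, 20),
        within_module_cor=0.8,
        noise_sd=0.4,
        seed=7,
    )
    datasets, truth = generate_multi_platform_study(cfg)
    return cfg, datasets, truth


def make_dataset(values: np.ndarray, groups=None, dataset_id="DS", annotate=True):
    """Small helper: wrap a raw matrix into an ExpressionDataset."""
    n, s = values.shape
    genes = [f"g{i}" for i in range(n)]
    cols = [f"{dataset_id}_s{j}" for j in range(s)]
    if groups is None:
        groups = ["SMA_I"] * (s // 2) + ["control"] * (s - s // 2)
    samples = pd.DataFrame(
        {"dataset_id": dataset_id, "group": groups}, index=pd.Index(cols, name="sample_id")
    )
    ann = None
    if annotate:
        ann = pd.DataFrame(
            {"symbol": genes, "entrez": range(1, n + 1)},
            index=pd.Index(genes, name="probe_id"),
        )
    return ExpressionDataset(
        dataset_id, pd.DataFrame(values, index=genes, columns=cols), samples, ann
    )
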